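"""Nearest-neighbour contact classification (i +/- k spectra).

A nucleosome is in contact when its nearest neighbour sits below the
contact threshold (default 11 nm, double disk radii).  Same-array
contacts are binned by chain separation k (capped at 4 with an 'i>4'
bucket); inter-array pairs are confirmed as trans when no resolved
linker joins the arrays and the terminal nucleosomes of the two arrays
are farther apart than the trans threshold; otherwise they are reported
as unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CONTACT_NM, TRANS_NM
from .io_model import Scene
from .stereology import nearest_neighbors

CATEGORIES = ("i1", "i2", "i3", "i4", "i>4", "trans", "unresolved", "none")


@dataclass
class ContactSpectrum:
    """Per-category fractions of total nucleosomes."""

    counts: dict[str, int]
    n_total: int
    sds: dict[str, float] = field(default_factory=dict)

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: self.counts.get(c, 0) / self.n_total for c in CATEGORIES}

    @staticmethod
    def from_labels(labels, n_total: int | None = None) -> "ContactSpectrum":
        labels = list(labels)
        counts = {c: labels.count(c) for c in CATEGORIES}
        return ContactSpectrum(counts=counts, n_total=n_total or len(labels))


def _category_for_k(k: int) -> str:
    return f"i{k}" if k <= 4 else "i>4"


def classify_contacts(
    scene: Scene,
    contact_nm: float = CONTACT_NM,
    trans_nm: float = TRANS_NM,
) -> tuple[pd.DataFrame, ContactSpectrum]:
    """Classify each nucleosome by its single nearest neighbour.

    Returns the per-nucleosome table (with category and k) and the
    aggregated spectrum.  Classification is exhaustive and exclusive.
    """
    df = scene.poses.df.reset_index(drop=True)
    pts = scene.poses.centroids()
    n_dist, n_idx = nearest_neighbors(scene)

    terminals: dict[str, np.ndarray] = {}
    for array_id, sub in df.groupby("array_id", sort=False):
        sub = sub.sort_values("nuc_index")
        terminals[array_id] = pts[[sub.index[0], sub.index[-1]]]

    labels = []
    for i in range(len(df)):
        j = n_idx[i]
        if j < 0 or not np.isfinite(n_dist[i]) or n_dist[i] >= contact_nm:
            labels.append("none")
            continue
        a_i = df.at[i, "array_id"]
        a_j = df.at[j, "array_id"]
        if a_i == a_j:
            k = abs(int(df.at[i, "nuc_index"]) - int(df.at[j, "nuc_index"]))
            labels.append(_category_for_k(k))
        else:
            tdist = np.linalg.norm(
                terminals[a_i][:, None, :] - terminals[a_j][None, :, :], axis=2
            )
            labels.append("trans" if tdist.min() > trans_nm else "unresolved")

    out = df[["array_id", "nuc_index"]].copy()
    out["N"] = n_dist
    out["nearest_row"] = n_idx
    out["category"] = labels
    return out, ContactSpectrum.from_labels(labels)


def fold_change(
    crosslinked: ContactSpectrum, control: ContactSpectrum
) -> dict[str, float | None]:
    """Per-category ratio of fractions, crosslinked over control.

    A zero control count is replaced by the documented pseudo-fraction
    0.5 / n_control; categories absent from both are reported as None.
    """
    if control.n_total == 0:
        raise ValueError("control spectrum has n = 0")
    out: dict[str, float | None] = {}
    for c in CATEGORIES:
        fx = crosslinked.fractions.get(c, 0.0)
        fc = control.fractions.get(c, 0.0)
        if fx == 0.0 and fc == 0.0:
            out[c] = None
        elif fc == 0.0:
            out[c] = fx / (0.5 / control.n_total)
        else:
            out[c] = fx / fc
    return out


def spectrum_from_ensemble(ensemble, contact_nm: float = CONTACT_NM) -> ContactSpectrum:
    """Contact spectrum of simulated core centroids, averaged over frames.

    Applies the same nearest-neighbour classification as the experimental
    pipeline to each sampled configuration; a single simulated fiber has
    no trans category.
    """
    core_pos = np.asarray(ensemble.core_positions)  # (n_frames, n_cores, 3)
    if core_pos.ndim != 3 or core_pos.shape[0] == 0:
        raise ValueError("ensemble is empty")
    n_frames, n_cores, _ = core_pos.shape
    counts = {c: 0 for c in CATEGORIES}
    for f in range(n_frames):
        p = core_pos[f]
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        j = np.argmin(d, axis=1)
        nd = d[np.arange(n_cores), j]
        for i in range(n_cores):
            if nd[i] >= contact_nm:
                counts["none"] += 1
            else:
                counts[_category_for_k(abs(i - j[i]))] += 1
    return ContactSpectrum(counts=counts, n_total=n_frames * n_cores)
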