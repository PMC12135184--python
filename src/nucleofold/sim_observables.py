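"""Observables on simulated fiber ensembles.

Packing ratio (nucleosomes per 11 nm of fiber axis), i +/- k interaction
profiles from the full pairwise contact matrix, per-core linker stem
indices, fan-plot positional distributions in the core body frame, and
tail-partner fractions.  All observables are invariant under global
rigid rotation/translation of every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CONTACT_NM, STEM_NM
from .mesoscale import Ensemble, T_CORE, T_LH, T_LINKER, T_TAIL

#: fiber unit length for the packing ratio, nm
PACKING_UNIT_NM = 11.0

#: minimum beads per linker for stem eligibility (> 26 bp)
STEM_MIN_BEADS = 3


def _stack_core_positions(ensembles) -> np.ndarray:
    if hasattr(ensembles, "core_positions"):
        ensembles = [ensembles]
    return np.concatenate([np.asarray(e.core_positions) for e in ensembles], axis=0)


def packing_ratio(
    ensembles, min_axis_variance: float = 0.60
) -> dict:
    """Nucleosomes per 11 nm of fiber axis, averaged over frames.

    Per frame the fiber axis is the first principal component of the core
    centroids and the fiber length is the extent of the centroid
    projections on it.  Degenerate frames (coincident centroids) are
    skipped and counted; frames whose axis explains less than
    ``min_axis_variance`` of the positional variance are flagged as bent.
    """
    core_pos = _stack_core_positions(ensembles)
    n_frames, n_cores, _ = core_pos.shape
    if n_cores < 3:
        raise ValueError("packing ratio needs at least 3 cores")
    ratios = []
    n_skipped = 0
    n_bent = 0
    for f in range(n_frames):
        p = core_pos[f] - core_pos[f].mean(axis=0)
        cov = p.T @ p / n_cores
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] < 1e-9:
            n_skipped += 1
            continue
        axis = evecs[:, -1]
        proj = p @ axis
        length = proj.max() - proj.min()
        if length < 1e-9:
            n_skipped += 1
            continue
        if evals[-1] / max(evals.sum(), 1e-12) < min_axis_variance:
            n_bent += 1
        ratios.append(n_cores * PACKING_UNIT_NM / length)
    ratios = np.asarray(ratios)
    return dict(
        mean=float(ratios.mean()) if len(ratios) else np.nan,
        sd=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        n_frames=len(ratios),
        n_skipped=n_skipped,
        n_bent_flagged=n_bent,
    )


def interaction_pattern(ensembles, contact_nm: float = CONTACT_NM) -> dict:
    """i +/- k contact frequency profile from the full pairwise matrix.

    Every core pair with centroid distance below the threshold is counted
    into its |i - j| bin (not only nearest neighbours); frequencies are
    normalized per nucleosome per frame.  The full (i, j) contact
    probability matrix is also returned.
    """
    core_pos = _stack_core_positions(ensembles)
    n_frames, n_cores, _ = core_pos.shape
    if n_frames == 0:
        raise ValueError("empty ensemble")
    matrix = np.zeros((n_cores, n_cores))
    freq = np.zeros(n_cores)
    for f in range(n_frames):
        p = core_pos[f]
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
        contact = d < contact_nm
        np.fill_diagonal(contact, False)
        matrix += contact
        i, j = np.nonzero(np.triu(contact))
        for k in np.abs(i - j):
            freq[k] += 1
    matrix /= n_frames
    freq /= n_frames * n_cores
    ks = np.arange(1, n_cores)
    return dict(k=ks, frequency=freq[1:], matrix=matrix)


def _linker_beads_of_core(ensemble: Ensemble, core: int):
    """(entry bead indices, exit bead indices), each ordered outward."""
    sys_ = ensemble.system
    nc = sys_.template.n_cores
    entry = exit_ = np.array([], dtype=int)
    if core > 0:
        li = core - 1
        s0, nb = int(sys_.linker_start[li]), int(sys_.linker_len[li])
        entry = np.arange(s0 + nb - 1, s0 - 1, -1)  # reversed: outward from core
    if core < nc - 1:
        li = core
        s0, nb = int(sys_.linker_start[li]), int(sys_.linker_len[li])
        exit_ = np.arange(s0, s0 + nb)
    return entry, exit_


def _to_core_frame(ensemble: Ensemble, core: int, idx: np.ndarray) -> np.ndarray:
    """Bead trajectories transformed into the core body frame.

    Returns (n_frames, len(idx), 3).
    """
    pos = np.asarray(ensemble.bead_positions)[:, idx, :]
    cpos = np.asarray(ensemble.core_positions)[:, core, :]
    crot = np.asarray(ensemble.core_rotations)[:, core, :, :]
    rel = pos - cpos[:, None, :]
    return np.einsum("fji,fbj->fbi", crot, rel)


@dataclass
class StemRecord:
    core: int
    eligible: bool
    index: float | None
    pair_distances: np.ndarray | None


def stem_index(
    ensemble: Ensemble, core: int, threshold_nm: float = STEM_NM
) -> StemRecord:
    """Stem-formation index for one core over a single trajectory.

    Bead j of the entry linker is paired with bead j of the exit linker
    (counted outward from the core); the index is the fraction of pairs
    whose trajectory-mean positions (in the core body frame) are closer
    than the threshold.  Cores need both linkers >= 3 beads (> 26 bp) to
    be eligible.
    """
    entry, exit_ = _linker_beads_of_core(ensemble, core)
    if len(entry) < STEM_MIN_BEADS or len(exit_) < STEM_MIN_BEADS:
        return StemRecord(core=core, eligible=False, index=None, pair_distances=None)
    n_pairs = min(len(entry), len(exit_))
    mean_entry = _to_core_frame(ensemble, core, entry[:n_pairs]).mean(axis=0)
    mean_exit = _to_core_frame(ensemble, core, exit_[:n_pairs]).mean(axis=0)
    dist = np.linalg.norm(mean_entry - mean_exit, axis=1)
    return StemRecord(
        core=core,
        eligible=True,
        index=float(np.mean(dist < threshold_nm)),
        pair_distances=dist,
    )


def stem_report(ensemble: Ensemble, threshold_nm: float = STEM_NM) -> list[StemRecord]:
    """Stem indices for every core of a single trajectory."""
    return [
        stem_index(ensemble, c, threshold_nm)
        for c in range(ensemble.system.template.n_cores)
    ]


def fan_distribution(
    ensemble: Ensemble,
    core: int,
    bins: int = 40,
    extent_nm: float = 25.0,
) -> dict:
    """Linker DNA positional distribution in the core body frame.

    Projects both flanking linkers' bead positions onto the nucleosome
    plane (body x-y) for every frame of a single trajectory; returns the
    cumulative 2D histogram and the trajectory-mean position per bead.
    """
    entry, exit_ = _linker_beads_of_core(ensemble, core)
    idx = np.concatenate([entry, exit_]).astype(int)
    if len(idx) == 0:
        edges = np.linspace(-extent_nm, extent_nm, bins + 1)
        return dict(hist=np.zeros((bins, bins)), x_edges=edges, y_edges=edges,
                    mean_entry=np.zeros((0, 3)), mean_exit=np.zeros((0, 3)))
    body = _to_core_frame(ensemble, core, idx)
    pts = body.reshape(-1, 3)
    edges = np.linspace(-extent_nm, extent_nm, bins + 1)
    hist, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges])
    mean_all = body.mean(axis=0)
    return dict(
        hist=hist,
        x_edges=xe,
        y_edges=ye,
        mean_entry=mean_all[: len(entry)],
        mean_exit=mean_all[len(entry):],
    )


TAIL_CATEGORIES = ("tail_linker_dna", "tail_core", "tail_tail", "tail_lh", "free")


def tail_interaction_fractions(
    ensembles, cutoff_nm: float = 2.0
) -> dict[str, float]:
    """Nearest non-parent partner category per tail bead, averaged.

    Categories: linker DNA, non-parental core pseudo-charges, other-core
    tails, LH, or free (nothing within the cutoff).  Fractions sum to 1.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    counts = {c: 0 for c in TAIL_CATEGORIES}
    total = 0
    for ens in ensembles:
        sys_ = ens.system
        tails = np.where(sys_.typ == T_TAIL)[0]
        if len(tails) == 0:
            raise ValueError("template has no tail beads")
        others = np.arange(sys_.n_beads)
        typ = sys_.typ
        owner = sys_.owner
        cat_of_type = {
            T_LINKER: "tail_linker_dna",
            T_CORE: "tail_core",
            T_TAIL: "tail_tail",
            T_LH: "tail_lh",
        }
        for f in range(ens.n_frames):
            pos = ens.bead_positions[f]
            d = np.linalg.norm(pos[tails][:, None, :] - pos[None, :, :], axis=2)
            # exclude self and same-parent beads
            same_parent = owner[tails][:, None] == owner[None, :]
            d[same_parent] = np.inf
            jmin = np.argmin(d, axis=1)
            dmin = d[np.arange(len(tails)), jmin]
            for t in range(len(tails)):
                total += 1
                if dmin[t] > cutoff_nm:
                    counts["free"] += 1
                else:
                    counts[cat_of_type[int(typ[jmin[t]])]] += 1
    return {c: counts[c] / total for c in TAIL_CATEGORIES}
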