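"""Per-nucleosome geometric descriptors and exclusion rules.

For each nucleosome: center-to-center distance D to the next nucleosome
in its chain, distance N to the nearest nucleosome anywhere in the scene,
bend angle alpha at the nucleosome between its chain neighbours, plane
angle beta to the next nucleosome, and plane angle para to the nearest
nucleosome.  Plane angles are unsigned and folded to [0, 90] deg because
fitted normals have arbitrary sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .constants import BOUNDARY_NM, STACK_N_NM, STACK_PARA_DEG
from .io_model import Scene


def _folded_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals folded to [0, 90] via |cos|."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _vertex_angle_deg(a: np.ndarray, v: np.ndarray, b: np.ndarray) -> float:
    """Angle at vertex v between segments v->a and v->b, in [0, 180]."""
    u1 = a - v
    u2 = b - v
    c = float(np.dot(u1, u2)) / (np.linalg.norm(u1) * np.linalg.norm(u2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def nearest_neighbors(scene: Scene) -> tuple[np.ndarray, np.ndarray]:
    """Nearest other nucleosome per nucleosome over the whole scene.

    Returns (distances, indices) into the pose table; ties are broken by
    lowest (array_id, nuc_index) ordering.
    """
    df = scene.poses.df
    pts = scene.poses.centroids()
    n = len(pts)
    if n < 2:
        return np.full(n, np.nan), np.full(n, -1, dtype=int)
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=min(8, n))
    order = np.lexsort((df["nuc_index"].to_numpy(), df["array_id"].to_numpy()))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    best_d = np.full(n, np.inf)
    best_i = np.full(n, -1, dtype=int)
    for i in range(n):
        for d, j in zip(dist[i], idx[i]):
            if j == i:
                continue
            if d < best_d[i] - 1e-12 or (
                abs(d - best_d[i]) <= 1e-12 and rank[j] < rank[best_i[i]]
            ):
                best_d[i] = d
                best_i[i] = j
    return best_d, best_i


def compute_geometry(scene: Scene) -> pd.DataFrame:
    """Compute D, N, alpha, beta and para for every nucleosome in a scene.

    Returns one record per nucleosome; descriptors that are undefined at
    chain ends are NaN.  Exclusion flags are *not* applied here (see
    :func:`apply_exclusions`).
    """
    df = scene.poses.df.reset_index(drop=True)
    pts = scene.poses.centroids()
    nrm = scene.poses.normals()
    n_dist, n_idx = nearest_neighbors(scene)

    records = []
    for array_id, sub in df.groupby("array_id", sort=False):
        sub = sub.sort_values("nuc_index")
        rows = sub.index.to_numpy()
        m = len(rows)
        for pos_in_chain, row in enumerate(rows):
            D = alpha = beta = np.nan
            if pos_in_chain < m - 1:
                nxt = rows[pos_in_chain + 1]
                D = float(np.linalg.norm(pts[nxt] - pts[row]))
                beta = _folded_angle_deg(nrm[row], nrm[nxt])
            if 0 < pos_in_chain < m - 1:
                alpha = _vertex_angle_deg(
                    pts[rows[pos_in_chain - 1]], pts[row], pts[rows[pos_in_chain + 1]]
                )
            j = n_idx[row]
            para = _folded_angle_deg(nrm[row], nrm[j]) if j >= 0 else np.nan
            records.append(
                dict(
                    array_id=array_id,
                    nuc_index=int(df.at[row, "nuc_index"]),
                    D=D,
                    N=float(n_dist[row]) if np.isfinite(n_dist[row]) else np.nan,
                    nearest_array=df.at[j, "array_id"] if j >= 0 else None,
                    nearest_index=int(df.at[j, "nuc_index"]) if j >= 0 else -1,
                    alpha=alpha,
                    beta=beta,
                    para=para,
                    near_boundary=bool(df.at[row, "near_boundary"]),
                    linker_resolved=bool(df.at[row, "linker_to_next_resolved"]),
                    excluded=False,
                    exclusion_reason="",
                )
            )
    return pd.DataFrame(records)


@dataclass
class ExclusionAudit:
    n_total: int
    n_boundary_removed: int
    n_d_dropped_unresolved: int
    n_alpha_dropped: int
    n_beta_dropped: int

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        if self.n_total:
            d["pct_boundary"] = 100.0 * self.n_boundary_removed / self.n_total
        return d


def apply_exclusions(
    records: pd.DataFrame,
    scene: Scene | None = None,
    boundary_nm: float = BOUNDARY_NM,
    drop_unresolved: bool = True,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply boundary and unresolved-linker exclusions.

    Boundary-flagged nucleosomes are removed entirely.  For unresolved
    linkers, only D, alpha and beta are dropped (N and para are kept):
    D and beta of the upstream nucleosome, and alpha of both flanking
    nucleosomes.
    """
    df = records.copy()
    n_total = len(df)
    boundary_mask = df["near_boundary"].astype(bool)
    df = df[~boundary_mask].copy()

    n_d = n_a = n_b = 0
    if drop_unresolved:
        key = df.set_index(["array_id", "nuc_index"])["linker_resolved"].to_dict()
        for i in df.index:
            a = df.at[i, "array_id"]
            k = df.at[i, "nuc_index"]
            up_unres = not df.at[i, "linker_resolved"]
            prev_unres = not key.get((a, k - 1), True)
            if up_unres and np.isfinite(df.at[i, "D"]):
                df.at[i, "D"] = np.nan
                n_d += 1
            if up_unres and np.isfinite(df.at[i, "beta"]):
                df.at[i, "beta"] = np.nan
                n_b += 1
            if (up_unres or prev_unres) and np.isfinite(df.at[i, "alpha"]):
                df.at[i, "alpha"] = np.nan
                n_a += 1
    audit = ExclusionAudit(
        n_total=n_total,
        n_boundary_removed=int(boundary_mask.sum()),
        n_d_dropped_unresolved=n_d,
        n_alpha_dropped=n_a,
        n_beta_dropped=n_b,
    )
    return df, audit


def stacked_fraction(
    records: pd.DataFrame,
    para_max_deg: float = STACK_PARA_DEG,
    n_max_nm: float = STACK_N_NM,
) -> tuple[float | None, pd.DataFrame, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Fraction of nucleosomes with para < para_max and N < n_max.

    Returns (fraction or None when undefined, the qualifying records, and
    a 2D (N, para) histogram for plotting).
    """
    ok = records.dropna(subset=["N", "para"])
    hist = np.histogram2d(
        ok["N"].to_numpy(), ok["para"].to_numpy(),
        bins=[np.arange(0, 41, 1.0), np.arange(0, 91, 2.5)],
    )
    if len(ok) == 0:
        return None, ok, hist
    mask = (ok["para"] < para_max_deg) & (ok["N"] < n_max_nm)
    return float(mask.mean()), ok[mask], hist


_DESCRIPTORS = ("D", "N", "alpha", "beta", "para")


def summarize(records: pd.DataFrame, group_col: str = "sample_id") -> dict:
    """Per-group mean/SD/n for each descriptor plus pairwise Welch-t and
    Kolmogorov-Smirnov p-values and percent changes between groups."""
    groups = {}
    for g, sub in records.groupby(group_col, sort=False):
        entry = {}
        for d in _DESCRIPTORS:
            vals = sub[d].dropna().to_numpy()
            if len(vals) < 2:
                entry[d] = dict(n=len(vals), note="too few values")
            else:
                entry[d] = dict(
                    mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=len(vals)
                )
        groups[g] = entry
    names = list(groups)
    tests = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pair = {}
            for d in _DESCRIPTORS:
                va = records.loc[records[group_col] == a, d].dropna().to_numpy()
                vb = records.loc[records[group_col] == b, d].dropna().to_numpy()
                if len(va) < 2 or len(vb) < 2:
                    continue
                t = stats.ttest_ind(va, vb, equal_var=False)
                ks = stats.ks_2samp(va, vb)
                pct = 100.0 * (vb.mean() - va.mean()) / abs(va.mean())
                pair[d] = dict(
                    welch_p=float(t.pvalue), ks_p=float(ks.pvalue),
                    pct_change=float(pct),
                )
            tests[f"{a} vs {b}"] = pair
    return dict(groups=groups, tests=tests)
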