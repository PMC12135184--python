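"""Open-DNA tracing calculus: O, S, E -> C and signed L.

O is the traced open-DNA length between the start/end peel points (bp at
0.34 nm/bp); S and E are the peeled segments at the upstream exit and
downstream entry.  L = O - S - E (negative when cores overlap); each
core's constrained length is C = 146 - S(exit flank) - E(entry flank),
with 0 for a terminal core's missing flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CORE_BP, NM_PER_BP
from .io_model import Scene, parse_points

#: cores with C below this are flagged as suspicious peels
C_SUSPICIOUS_BP = 100.0


def polyline_length_bp(points: np.ndarray) -> float:
    """Total polyline length in bp (segment sum in nm divided by 0.34)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(seg.sum() / NM_PER_BP)


def decompose(O: float, S: float, E: float) -> tuple[float, float, float]:
    """Split an open length into (L, exit-side C loss, entry-side C loss).

    L = O - S - E may be negative (overlapping cores) and is never
    clamped.  The returned contributions are the amounts subtracted from
    the 146 bp core on the exit (S) and entry (E) flanks.
    """
    if S < 0 or E < 0:
        raise ValueError("S and E must be >= 0")
    return O - S - E, S, E


@dataclass
class LinkerMeasurement:
    array_id: str
    linker_index: int
    O_bp: float
    S_bp: float
    E_bp: float
    L_bp: float
    resolved: bool


def measure_scene(scene: Scene) -> pd.DataFrame:
    """Measure every traced linker of a scene: O from the polyline, then
    the O/S/E decomposition."""
    if scene.paths is None:
        raise ValueError("scene has no traced paths")
    rows = []
    for _, rec in scene.paths.df.iterrows():
        pts = parse_points(rec["points"])
        O = polyline_length_bp(pts) if len(pts) >= 2 else np.nan
        L, _, _ = decompose(O, rec["S_bp"], rec["E_bp"]) if np.isfinite(O) else (np.nan,) * 3
        rows.append(
            dict(
                array_id=rec["array_id"],
                linker_index=int(rec["linker_index"]),
                O_bp=O,
                S_bp=float(rec["S_bp"]),
                E_bp=float(rec["E_bp"]),
                L_bp=L,
                resolved=bool(rec["resolved"]),
            )
        )
    return pd.DataFrame(rows)


def per_core_c(measurements: pd.DataFrame, core_bp: float = CORE_BP) -> pd.DataFrame:
    """Constrained core length per nucleosome.

    Core i of an array loses S of linker i (its exit flank) and E of
    linker i-1 (its entry flank); terminal cores use 0 for the missing
    flank.  Cores with any unresolved existing flank are reported with
    C = NaN (excluded from statistics), mirroring density-gap exclusions.
    """
    rows = []
    for array_id, sub in measurements.groupby("array_id", sort=False):
        sub = sub.sort_values("linker_index")
        by_idx = {int(r["linker_index"]): r for _, r in sub.iterrows()}
        n_cores = max(by_idx) + 1
        for i in range(1, n_cores + 1):
            exit_l = by_idx.get(i)  # linker leaving core i
            entry_l = by_idx.get(i - 1)  # linker arriving at core i
            complete = all(
                l is None or bool(l["resolved"]) for l in (exit_l, entry_l)
            )
            if complete:
                c = core_bp
                c -= float(exit_l["S_bp"]) if exit_l is not None else 0.0
                c -= float(entry_l["E_bp"]) if entry_l is not None else 0.0
            else:
                c = np.nan
            rows.append(
                dict(
                    array_id=array_id,
                    nuc_index=i,
                    C_bp=c,
                    suspicious=bool(np.isfinite(c) and c < C_SUSPICIOUS_BP),
                )
            )
    return pd.DataFrame(rows)


def per_array_averages(
    measurements: pd.DataFrame, core_bp: float = CORE_BP
) -> pd.DataFrame:
    """Arithmetic per-array averages of L and C over resolved linkers.

    Arrays with no resolved linker are absent from the output.
    """
    cores = per_core_c(measurements, core_bp)
    rows = []
    for array_id, sub in measurements.groupby("array_id", sort=False):
        ok = sub[sub["resolved"] & np.isfinite(sub["L_bp"])]
        if len(ok) == 0:
            continue
        c_ok = cores.loc[
            (cores["array_id"] == array_id) & np.isfinite(cores["C_bp"]), "C_bp"
        ]
        rows.append(
            dict(
                array_id=array_id,
                L_av=float(ok["L_bp"].mean()),
                C_av=float(c_ok.mean()) if len(c_ok) else np.nan,
                n_linkers=len(ok),
                n_cores=len(c_ok),
            )
        )
    return pd.DataFrame(rows)


def nrl_estimate(mean_l: float, core_bp: float = CORE_BP) -> float:
    """Nucleosome repeat length: core DNA length plus mean linker length."""
    return core_bp + mean_l


def correlation_checks(measurements: pd.DataFrame) -> dict:
    """Pearson/Spearman correlations: C vs L per nucleosome and per array,
    and per-array mean L vs array size."""
    ok = measurements[measurements["resolved"] & np.isfinite(measurements["L_bp"])]
    if len(ok) < 3:
        raise ValueError("need at least 3 paired values")
    cores = per_core_c(measurements)
    # pair each linker's L with the C of its upstream core
    merged = ok.merge(
        cores.rename(columns={"nuc_index": "linker_index"}),
        on=["array_id", "linker_index"],
    ).dropna(subset=["C_bp"])
    out: dict = {}

    def corr(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return None
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        return dict(
            pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
            spearman_r=float(sr.statistic), spearman_p=float(sr.pvalue), n=len(x),
        )

    out["C_vs_L_per_nucleosome"] = corr(merged["C_bp"], merged["L_bp"])
    per_array = per_array_averages(measurements).dropna(subset=["C_av"])
    out["C_vs_L_per_array"] = corr(per_array["C_av"], per_array["L_av"])
    sizes = measurements.groupby("array_id")["linker_index"].max() + 1
    pa = per_array.set_index("array_id")
    common = pa.index.intersection(sizes.index)
    out["Lav_vs_array_size"] = corr(pa.loc[common, "L_av"], sizes.loc[common])
    return out
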