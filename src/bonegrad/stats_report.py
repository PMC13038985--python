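"""Structure-function statistics: pairing, Pearson correlation, summary.

Microstructural measurements (porosity, mean canal diameter per
longitudinal position) are paired with position-matched compressive moduli
by nearest-position matching, and their linear association is quantified
with the Pearson product-moment coefficient and a two-tailed p-value from
the exact t transform, t = r * sqrt((n-2) / (1 - r^2)) with n - 2 degrees
of freedom.  Both pooled and per-replicate analyses are reported; no
multiple-testing correction is applied by default (a Holm option exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedRecord",
    "CorrelationResult",
    "pair_by_position",
    "pearson",
    "summarize",
]

_VARIABLE_PAIRS = [
    ("porosity", "modulus1"),
    ("porosity", "modulus2"),
    ("mean_canal_diameter_um", "modulus1"),
    ("mean_canal_diameter_um", "modulus2"),
]


@dataclass
class PairedRecord:
    position: float  # mm
    porosity: float
    mean_canal_diameter: float
    modulus1: float
    modulus2: float
    max_strength: float
    replicate_id: str


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    variables: tuple[str, str]


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-tailed t-distribution p-value.

    Requires n >= 3 and nonzero variance in both series.  Perfect linear
    association returns r = ±1 with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0 or sy == 0:
        name = "x" if sx == 0 else "y"
        raise ValueError(f"zero variance in {name}; correlation undefined")
    r = float(xc @ yc) / np.sqrt(sx * sy)
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - r * r < 1e-15:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n, variables=("x", "y"))


def pair_by_position(
    structure_table: pd.DataFrame,
    mech_table: pd.DataFrame,
    tolerance: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nearest-position pairing of structure and mechanics rows.

    Both tables must carry ``position_mm`` on the same distal-origin axis.
    Each mechanics row pairs with its nearest structural row within
    ``tolerance`` mm; ties at equal distance go to the smaller position.
    Returns (paired, unmatched) — unmatched mechanics rows are reported,
    never silently dropped.
    """
    if "position_mm" not in structure_table or "position_mm" not in mech_table:
        raise ValueError("both tables need a position_mm column")
    s = structure_table.sort_values("position_mm", ignore_index=True)
    spos = s["position_mm"].to_numpy(dtype=float)
    paired_rows = []
    unmatched_rows = []
    for _, mrow in mech_table.iterrows():
        d = np.abs(spos - float(mrow["position_mm"]))
        best = float(d.min())
        if best > tolerance:
            row = mrow.to_dict()
            row["unmatched_reason"] = f"nearest structure row {best:.3f} mm away"
            unmatched_rows.append(row)
            continue
        # smallest index among minima = smallest position (table is sorted)
        j = int(np.flatnonzero(np.isclose(d, best, rtol=0.0, atol=1e-12))[0])
        srow = s.iloc[j].to_dict()
        mdict = mrow.to_dict()
        row: dict = {}
        for k, v in srow.items():
            if k == "position_mm":
                row["structure_position_mm"] = float(v)
            else:
                row[f"structure_{k}" if k in mdict else k] = v
        for k, v in mdict.items():
            if k == "position_mm":
                row["position_mm"] = float(v)
            else:
                row[f"mech_{k}" if k in srow else k] = v
        row["pairing_distance_mm"] = best
        paired_rows.append(row)
    paired = pd.DataFrame(paired_rows)
    unmatched = pd.DataFrame(unmatched_rows)
    return paired, unmatched


def _corr_row(df: pd.DataFrame, vx: str, vy: str, scope: str) -> dict:
    row = {"scope": scope, "x": vx, "y": vy, "r": np.nan, "p": np.nan,
           "n": 0, "note": ""}
    if vx not in df or vy not in df:
        row["note"] = "missing column"
        return row
    sub = df[[vx, vy]].dropna()
    row["n"] = len(sub)
    try:
        res = pearson(sub[vx].to_numpy(), sub[vy].to_numpy())
    except ValueError as exc:
        row["note"] = str(exc)
        return row
    row["r"] = res.r
    row["p"] = res.p
    return row


def summarize(
    paired: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    alpha: float = 0.05,
    holm: bool = False,
    spearman: bool = False,
) -> dict:
    """Correlation report for pooled and per-replicate data.

    Emits porosity/diameter against modulus 1/2 for the pooled table and
    for each ``replicate_id`` group.  Failures (too few pairs, zero
    variance) degrade to NA rows with a reason.  ``profiles``, when given,
    is passed through as the longitudinal co-variation table.  A Spearman
    column can be added as an extension for monotone non-linear links.
    """
    if paired.empty:
        raise ValueError("no paired records")
    rows = [_corr_row(paired, vx, vy, "pooled") for vx, vy in _VARIABLE_PAIRS]
    if "replicate_id" in paired:
        for rid, grp in paired.groupby("replicate_id"):
            rows.extend(_corr_row(grp, vx, vy, f"replicate:{rid}") for vx, vy in _VARIABLE_PAIRS)
    table = pd.DataFrame(rows)
    if spearman:
        rs = []
        for _, row in table.iterrows():
            scope = row["scope"]
            df = paired if scope == "pooled" else paired[
                paired["replicate_id"].astype(str) == scope.split(":", 1)[1]
            ]
            sub = df[[row["x"], row["y"]]].dropna() if row["x"] in df and row["y"] in df else None
            if sub is None or len(sub) < 3:
                rs.append(np.nan)
            else:
                rs.append(float(sps.spearmanr(sub[row["x"]], sub[row["y"]]).statistic))
        table["spearman_r"] = rs
    if holm:
        pooled = table["scope"] == "pooled"
        pvals = table.loc[pooled, "p"].to_numpy()
        ok = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            order = np.argsort(pvals[ok])
            m = ok.sum()
            stepped = np.maximum.accumulate((m - np.arange(m)) * pvals[ok][order])
            out = np.empty(m)
            out[order] = np.minimum(stepped, 1.0)
            adj[ok] = out
        table.loc[pooled, "p_holm"] = adj
    table["significant"] = table["p"] < alpha
    report = {"correlations": table, "alpha": alpha}
    if profiles is not None:
        report["longitudinal_covariation"] = profiles
    return report
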