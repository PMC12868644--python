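"""Paired differential-expression screen over sliding developmental windows.

Log2 expression values from matched case/control sample pairs, annotated
with an ordered developmental stage, are compared with a paired two-tailed
t-test inside each sliding window of consecutive stages (default three
stages per window, stride one).  A gene is flagged in a window when its
linear fold change is at least ``fc_threshold`` in either direction
(FC >= 1.3 or FC <= 1/1.3) AND the paired p value is below ``p_threshold``
(default 0.01).  Benjamini-Hochberg FDR q values are reported optionally.

Also includes the qPCR ΔCT relative-expression computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ScreenParams",
    "sliding_windows",
    "paired_de_screen",
    "delta_ct",
]


@dataclass(frozen=True)
class ScreenParams:
    fc_threshold: float = 1.3  # linear scale, applied two-sided
    p_threshold: float = 0.01
    window_size: int = 3
    fdr: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class ExpressionMatrix:
    """Log2 gene x sample expression with paired case/control design.

    ``values``: DataFrame indexed by gene, columns are sample ids.
    ``design``: DataFrame indexed by sample id with columns ``condition``
    ("DS" or "control"), ``pair`` and ``stage`` (ordered integers).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design rows: {sorted(missing)[:5]}")
        bad = set(self.design["condition"]) - {"DS", "control"}
        if bad:
            raise ValueError(f"unknown conditions: {bad}")
        for pair, grp in self.design.groupby("pair"):
            counts = grp["condition"].value_counts()
            if counts.get("DS", 0) != 1 or counts.get("control", 0) != 1:
                raise ValueError(
                    f"pair {pair!r} must have exactly one DS and one control sample"
                )

    @property
    def stages(self) -> list[int]:
        return sorted(self.design["stage"].unique())

    @classmethod
    def from_csv(cls, expr_path, design_path) -> "ExpressionMatrix":
        """Expression CSV (first column gene id) + design CSV
        (``sample,condition,pair,stage``)."""
        values = pd.read_csv(expr_path, index_col=0)
        design = pd.read_csv(design_path, index_col=0)
        return cls(values=values, design=design)


def sliding_windows(stages, window_size: int = 3) -> list[tuple]:
    """Consecutive groups of ``window_size`` stages with stride 1.

    ``n_stages - window_size + 1`` windows; e.g. nine stages at size three
    give seven windows.
    """
    stages = sorted(set(stages))
    if len(stages) < window_size:
        raise ValueError("fewer stages than the window size")
    return [tuple(stages[k:k + window_size])
            for k in range(len(stages) - window_size + 1)]


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-tailed paired t-test on per-gene difference rows.

    Degenerate rows (zero variance) follow the convention p = 1 when the
    mean difference is also zero, else p = 0.
    """
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    degenerate = sd == 0
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    return mean, p


def paired_de_screen(
    expr: ExpressionMatrix, params: ScreenParams | None = None
) -> pd.DataFrame:
    """Per-gene, per-window paired screen on log2 expression.

    Returns one row per gene x window with the mean paired log2 difference
    (DS minus control), the linear fold change 2**diff, the paired t-test
    p value, the optional BH q value (within window), the significance flag
    (|FC| gate AND p gate on the raw p) and the direction ("up"/"down").
    Genes with missing values in any pair of a window are excluded from that
    window (with a warning).
    """
    params = params or ScreenParams()
    windows = sliding_windows(expr.stages, params.window_size)
    design = expr.design
    log_fc_gate = np.log2(params.fc_threshold)
    out = []
    for w_idx, window in enumerate(windows):
        samples = design[design["stage"].isin(window)]
        pairs = []
        for pair, grp in samples.groupby("pair"):
            if {"DS", "control"} <= set(grp["condition"]):
                pairs.append((pair,
                              grp[grp["condition"] == "DS"].index[0],
                              grp[grp["condition"] == "control"].index[0]))
        if len(pairs) < 3:
            raise ValueError(
                f"window {window}: need >= 3 complete pairs, found {len(pairs)}"
            )
        ds_cols = [p[1] for p in pairs]
        ct_cols = [p[2] for p in pairs]
        diffs = expr.values[ds_cols].to_numpy() - expr.values[ct_cols].to_numpy()
        complete = ~np.isnan(diffs).any(axis=1)
        if not complete.all():
            warnings.warn(
                f"window {window}: excluding {int((~complete).sum())} genes "
                "with missing values"
            )
        genes = expr.values.index[complete]
        mean, p = _paired_t(diffs[complete])
        fc = np.power(2.0, mean)
        flagged = (np.abs(mean) >= log_fc_gate) & (p < params.p_threshold)
        frame = pd.DataFrame({
            "gene": genes,
            "window": w_idx,
            "stages": [window] * len(genes),
            "n_pairs": len(pairs),
            "mean_log2_diff": mean,
            "fold_change": fc,
            "p_value": p,
            "significant": flagged,
            "direction": np.where(mean >= 0, "up", "down"),
        })
        if params.fdr:
            frame["q_value"] = multipletests(p, method="fdr_bh")[1]
        out.append(frame)
    return pd.concat(out, ignore_index=True)


def delta_ct(ct_gene, ct_reference):
    """Relative expression 2**(-(CT_gene - CT_reference)).

    Accepts scalars or arrays; group comparisons are ratios of group means
    of the returned relative expressions.
    """
    ct_gene = np.asarray(ct_gene, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if np.any(ct_gene <= 0) or np.any(ct_reference <= 0):
        raise ValueError("CT values must be positive")
    rel = np.power(2.0, -(ct_gene - ct_reference))
    return rel if rel.shape else float(rel)
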