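"""Label-free differential abundance between treatment and control groups,
plus z-score normalization for heatmaps, relative qPCR quantification
(2^-ddCt) and Kyte-Doolittle hydropathy.

Testing uses a two-sample Student's t-test (pooled variance; Welch by
flag) on log2 intensities with Benjamini-Hochberg adjustment.  Fold change
is the ratio of raw group means.  SEPs with fewer than two non-missing
values in either group are reported untested and excluded from the BH set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantConfig",
    "DdctInput",
    "differential_test",
    "ttest_two_sample",
    "bh_adjust",
    "row_zscore",
    "ddct",
    "gravy",
    "KYTE_DOOLITTLE",
]


@dataclass(frozen=True)
class QuantConfig:
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    log_transform: bool = True
    welch: bool = False
    median_center: bool = False


def ttest_two_sample(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance unless ``welch``."""
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: adj_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def differential_test(
    matrix: pd.DataFrame,
    treatment_cols: Sequence[str],
    control_cols: Sequence[str],
    cfg: QuantConfig = QuantConfig(),
) -> pd.DataFrame:
    """Per-row differential test of treatment vs control columns.

    Returns a frame indexed like ``matrix`` with columns mean_treatment,
    mean_control, fc, log2fc, t, p, adj_p, tested, class.  ``class`` is
    'up' iff fc > fc_up and adj_p < alpha, 'down' iff fc < fc_down and
    adj_p < alpha, else 'unchanged' ('untested' when not testable).
    """
    t_cols, c_cols = list(treatment_cols), list(control_cols)
    if set(t_cols) & set(c_cols):
        raise ValueError("treatment and control columns overlap")
    treat = matrix[t_cols].to_numpy(dtype=float)
    ctrl = matrix[c_cols].to_numpy(dtype=float)
    if np.all(np.isnan(treat)) or np.all(np.isnan(ctrl)):
        raise ValueError("a group is entirely missing")
    if cfg.median_center:
        all_cols = np.concatenate([treat, ctrl], axis=1)
        grand = np.nanmedian(all_cols)
        for block in (treat, ctrl):
            med = np.nanmedian(block, axis=0)
            block += grand - med

    n = matrix.shape[0]
    out = pd.DataFrame(index=matrix.index)
    out["mean_treatment"] = np.nanmean(treat, axis=1)
    out["mean_control"] = np.nanmean(ctrl, axis=1)
    out["fc"] = out["mean_treatment"] / out["mean_control"]
    out["log2fc"] = np.log2(out["fc"])

    tvals = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    tested = np.zeros(n, dtype=bool)
    for i in range(n):
        a = treat[i][~np.isnan(treat[i])]
        b = ctrl[i][~np.isnan(ctrl[i])]
        if a.size < 2 or b.size < 2:
            continue
        if cfg.log_transform:
            a, b = np.log2(a), np.log2(b)
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            tvals[i], pvals[i] = 0.0, 1.0
        else:
            tvals[i], pvals[i] = ttest_two_sample(a, b, welch=cfg.welch)
        tested[i] = True
    out["t"] = tvals
    out["p"] = pvals
    adj = np.full(n, np.nan)
    if tested.any():
        adj[tested] = bh_adjust(pvals[tested])
    out["adj_p"] = adj
    out["tested"] = tested

    cls = np.where(
        tested & (out["fc"] > cfg.fc_up) & (adj < cfg.alpha), "up",
        np.where(tested & (out["fc"] < cfg.fc_down) & (adj < cfg.alpha), "down",
                 np.where(tested, "unchanged", "untested")),
    )
    out["class"] = cls
    return out


def row_zscore(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row (x - mean)/SD with sample SD (ddof=1).

    Constant rows are returned as zeros and flagged in the second element.
    """
    x = matrix.to_numpy(dtype=float)
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / safe_sd
    z[constant, :] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(constant, index=matrix.index, name="constant_row"),
    )


@dataclass
class DdctInput:
    """Replicate-wise Ct values for a target and a reference gene (default
    reference label 'GroEL') in treated and control conditions."""

    target_treated: Sequence[float]
    reference_treated: Sequence[float]
    target_control: Sequence[float]
    reference_control: Sequence[float]
    reference_label: str = "GroEL"

    def __post_init__(self) -> None:
        arrays = [np.asarray(x, dtype=float) for x in (
            self.target_treated, self.reference_treated,
            self.target_control, self.reference_control)]
        if any(a.size == 0 for a in arrays[2:]) or arrays[1].size == 0:
            raise ValueError("missing reference or control Ct values")
        if len(self.target_treated) != len(self.reference_treated):
            raise ValueError("treated target/reference replicate counts differ")
        if len(self.target_control) != len(self.reference_control):
            raise ValueError("control target/reference replicate counts differ")
        for a in arrays:
            if np.any(~np.isfinite(a)) or np.any(a <= 0):
                raise ValueError("Ct values must be finite and positive")


def ddct(d: DdctInput) -> dict[str, float | np.ndarray]:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition (replicate-paired);
    ddCt_i = dCt_treated_i - mean(dCt_control); fold_i = 2^-ddCt_i.
    Returns per-replicate folds plus their mean and SD.
    """
    dct_t = np.asarray(d.target_treated, float) - np.asarray(d.reference_treated, float)
    dct_c = np.asarray(d.target_control, float) - np.asarray(d.reference_control, float)
    ddct_vals = dct_t - dct_c.mean()
    folds = 2.0 ** (-ddct_vals)
    return {
        "folds": folds,
        "fold_mean": float(folds.mean()),
        "fold_sd": float(folds.std(ddof=1)) if folds.size > 1 else 0.0,
        "ddct_mean": float(ddct_vals.mean()),
    }


KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def gravy(protein: str, hydrophobic_cutoff: float = 0.0) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle index per residue."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def is_hydrophobic(protein: str, cutoff: float = 0.0) -> bool:
    return gravy(protein) > cutoff
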