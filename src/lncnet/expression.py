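"""FPKM normalization, threshold-based differential-expression calling and
qPCR fold-change arithmetic.

Counts are normalized to FPKM (reads per kilobase of transcript per million
mapped reads).  Per-feature significance comes from a pluggable two-group
test — the default is Welch's t on log2(FPKM + 1) — followed by
Benjamini-Hochberg FDR control.  Calls are threshold-based: mRNA/lncRNA need
|log2FC| > 1 and q < 0.05; miRNA need |log2FC| > 1 and raw p < 0.05 (all
inequalities strict).  Fold change is oriented later-stage over earlier-stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .models import ValidationError
from .stats import bh_fdr  # re-exported as part of this module's surface

__all__ = [
    "ExpressionMatrix",
    "compute_fpkm",
    "log2_fold_change",
    "de_test",
    "register_de_test",
    "bh_fdr",
    "call_de",
    "differential_expression",
    "summarize_de",
    "ddct_relative_expression",
]

#: Stage labels of the ovarian-development design, in temporal order.
STAGES = ("IV", "V", "VI")

_P_FLOOR = 1e-300


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance table.

    ``values`` holds non-negative reals with feature ids as the index and
    sample ids as columns; ``kind`` tags the scale (``"counts"`` or
    ``"fpkm"``); ``lengths`` (bp per feature) is required to normalize counts.
    """

    values: pd.DataFrame
    kind: str = "counts"
    lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "fpkm"):
            raise ValidationError(f"kind must be 'counts' or 'fpkm', got {self.kind!r}")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.lengths is not None:
            self.lengths = self.lengths.astype(float)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def compute_fpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM[i, j] = counts[i, j] * 1e9 / (library_size[j] * length[i])."""
    if counts.kind != "counts":
        raise ValidationError("compute_fpkm expects a counts matrix")
    if counts.lengths is None:
        raise ValidationError("feature lengths are required for FPKM")
    missing = counts.features.difference(counts.lengths.index)
    if len(missing):
        raise ValidationError(f"missing length for feature(s): {list(missing)[:5]}")
    lib = counts.values.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample(s): {list(zero.index)}")
    lengths = counts.lengths.loc[counts.features]
    fpkm = counts.values.div(lib, axis=1).div(lengths, axis=0) * 1e9
    return ExpressionMatrix(values=fpkm, kind="fpkm", lengths=counts.lengths)


def log2_fold_change(a_mean: float, b_mean: float, pseudocount: float = 1.0) -> float:
    """log2((b + pc) / (a + pc)); positive means up in the second group.

    Returns NaN when both means and the pseudocount are zero.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if a_mean < 0 or b_mean < 0:
        raise ValidationError("means must be non-negative")
    num, den = b_mean + pseudocount, a_mean + pseudocount
    if num == 0 and den == 0:
        return float("nan")
    if num == 0 or den == 0:
        return float("-inf") if num == 0 else float("inf")
    return math.log2(num / den)


def _welch_t_log2(a: np.ndarray, b: np.ndarray) -> float:
    """Welch's t on log2(x + 1); ties (identical pooled values) give p = 1."""
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if np.ptp(la) == 0 and np.ptp(lb) == 0:
        return 1.0 if la[0] == lb[0] else _P_FLOOR
    p = _sps.ttest_ind(la, lb, equal_var=False).pvalue
    if not np.isfinite(p):  # degenerate variance
        return 1.0 if np.mean(la) == np.mean(lb) else _P_FLOOR
    return max(float(p), _P_FLOOR)


DE_TESTS: Dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "welch_t_log2": _welch_t_log2,
}


def register_de_test(name: str, fn: Callable[[np.ndarray, np.ndarray], float]) -> None:
    """Register an alternative per-feature two-group test under ``name``."""
    DE_TESTS[name] = fn


def de_test(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    comparison: Tuple[str, str],
    method: str = "welch_t_log2",
) -> pd.Series:
    """Two-sided p per feature for ``stage_a`` vs ``stage_b``.

    ``design`` is indexed by sample id with a ``stage`` column; both groups
    need >= 2 replicates.
    """
    stage_a, stage_b = comparison
    try:
        fn = DE_TESTS[method]
    except KeyError:
        raise ValidationError(f"unknown DE test {method!r}") from None
    cols_a = design.index[design["stage"] == stage_a].intersection(expr.samples)
    cols_b = design.index[design["stage"] == stage_b].intersection(expr.samples)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"comparison {stage_a} vs {stage_b}: each group needs >= 2 replicates"
        )
    a = expr.values[cols_a].to_numpy(dtype=float)
    b = expr.values[cols_b].to_numpy(dtype=float)
    return pd.Series(
        [fn(a[i], b[i]) for i in range(a.shape[0])], index=expr.features, name="p"
    )


def call_de(log2fc: float, p: float, q: float, feature_class: str) -> str:
    """Threshold call: 'up', 'down' or 'ns' (strict inequalities).

    mRNA/lncRNA gate on the BH q-value; miRNA on the raw p-value.
    """
    if feature_class in ("mRNA", "lncRNA"):
        sig = q < 0.05
    elif feature_class == "miRNA":
        sig = p < 0.05
    else:
        raise ValidationError(f"unknown feature class {feature_class!r}")
    if not np.isfinite(log2fc):
        return "ns"
    if sig and log2fc > 1.0:
        return "up"
    if sig and log2fc < -1.0:
        return "down"
    return "ns"


def differential_expression(
    counts: ExpressionMatrix,
    design: pd.DataFrame,
    comparisons: Sequence[Tuple[str, str]] = (("IV", "V"), ("V", "VI")),
    feature_class: str = "mRNA",
    pseudocount: float = 1.0,
    method: str = "welch_t_log2",
) -> pd.DataFrame:
    """Full DE table over the given stage comparisons.

    Columns: feature_id, class, comparison (``"A_vs_B"``), log2fc
    (B relative to A), p, q, call.
    """
    fpkm = compute_fpkm(counts) if counts.kind == "counts" else counts
    out = []
    for stage_a, stage_b in comparisons:
        label = f"{stage_a}_vs_{stage_b}"
        cols_a = design.index[design["stage"] == stage_a].intersection(fpkm.samples)
        cols_b = design.index[design["stage"] == stage_b].intersection(fpkm.samples)
        mean_a = fpkm.values[cols_a].mean(axis=1)
        mean_b = fpkm.values[cols_b].mean(axis=1)
        lfc = np.array(
            [log2_fold_change(a, b, pseudocount) for a, b in zip(mean_a, mean_b)]
        )
        p = de_test(fpkm, design, (stage_a, stage_b), method=method)
        q = bh_fdr(p.values)
        calls = [
            call_de(lfc[i], p.values[i], q[i], feature_class)
            for i in range(len(lfc))
        ]
        out.append(
            pd.DataFrame(
                {
                    "feature_id": fpkm.features,
                    "class": feature_class,
                    "comparison": label,
                    "log2fc": lfc,
                    "p": p.values,
                    "q": q,
                    "call": calls,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def summarize_de(results: pd.DataFrame) -> Dict[str, object]:
    """Headline DE statistics over one DE table.

    Reports per-comparison up/down/total counts, pairwise intersection sizes
    of the DE id sets, the cross-comparison *sum* of per-comparison totals
    (the convention used for headline totals, without deduplication) and the
    deduplicated *union* size.
    """
    per: Dict[str, Dict[str, int]] = {}
    sets: Dict[str, Set[str]] = {}
    for label, grp in results.groupby("comparison", sort=False):
        de = grp[grp["call"] != "ns"]
        per[label] = {
            "up": int((de["call"] == "up").sum()),
            "down": int((de["call"] == "down").sum()),
            "total": int(len(de)),
        }
        sets[label] = set(de["feature_id"])
    labels = list(per)
    inter = {
        f"{a}&{b}": len(sets[a] & sets[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    union: Set[str] = set().union(*sets.values()) if sets else set()
    return {
        "per_comparison": per,
        "intersection": inter,
        "sum": sum(v["total"] for v in per.values()),
        "union": len(union),
    }


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)[case] - (Ct_target - Ct_ref)[control];
    the result is the case/control fold change of the target, normalized to
    the reference gene.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(c) for c in cts):
        raise ValidationError("all Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
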