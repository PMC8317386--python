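"""Chromosome-instability scoring from per-nucleus FISH focus counts.

A near-tetraploid line carries 4 copies of the probed chromosomes per
nucleus; deviation from 4 after a round of mitosis marks a segregation
error. Two filters precede the rate: nuclei with 8 copies of either probed
chromosome are S/G2 cells that have replicated (excluded, not aberrant),
and nuclei with a robust-outlier volume are likewise removed. The induced
vs uninduced comparison is a Pearson chi-squared test on the 2×2
aberrant/normal table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, DomainError, UndefinedValueError

__all__ = [
    "ContingencyTable2x2", "apply_exclusions", "instability_rate",
    "chi2_2x2", "percent_change", "instability_report",
]

S_G2_COUNT = 8  # replicated tetraploid genome


@dataclass
class ContingencyTable2x2:
    """Aberrant/normal × group-A/group-B nucleus counts."""

    a: int  # aberrant, group A
    b: int  # normal,   group A
    c: int  # aberrant, group B
    d: int  # normal,   group B

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def apply_exclusions(
    records: pd.DataFrame,
    volume_rule: bool = True,
    mad_k: float = 2.0,
    count_cols: tuple[str, ...] = ("count_ch7", "count_ch11"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Flag S/G2 and volume-outlier nuclei; never deletes rows.

    A nucleus with ``S_G2_COUNT`` copies of *either* probed chromosome is
    flagged with reason ``"s_g2"``. With ``volume_rule``, remaining nuclei
    whose volume exceeds median + ``mad_k`` × (1.4826·MAD), computed within
    their group over non-S/G2 nuclei, are flagged ``"volume"``. Idempotent:
    re-applying to an already-flagged table reproduces the same flags.
    """
    out = records.copy()
    if out.empty:
        out["excluded"] = pd.Series(dtype=bool)
        out["exclude_reason"] = pd.Series(dtype=str)
        return out
    sg2 = np.zeros(len(out), dtype=bool)
    for col in count_cols:
        if col in out.columns:
            sg2 |= out[col].to_numpy() == S_G2_COUNT
    reason = np.where(sg2, "s_g2", "")

    if volume_rule:
        if "volume_um3" not in out.columns:
            raise DomainError("volume_rule requires a volume_um3 column")
        vol = out["volume_um3"].to_numpy(dtype=float)
        groups = out[group_col] if group_col in out.columns else pd.Series("_", index=out.index)
        for g in groups.unique():
            in_g = (groups == g).to_numpy()
            ref = vol[in_g & ~sg2]
            if ref.size == 0:
                continue
            med = np.median(ref)
            mad = np.median(np.abs(ref - med))
            cut = med + mad_k * 1.4826 * mad
            big = in_g & ~sg2 & (vol > cut)
            reason = np.where(big, "volume", reason)
    out["excluded"] = reason != ""
    out["exclude_reason"] = reason
    return out


def instability_rate(
    records: pd.DataFrame,
    chromosome: str = "count_ch7",
    euploid: int = 4,
) -> tuple[int, int, float]:
    """(aberrant, usable, rate %) of nuclei deviating from the euploid count.

    Operates on the non-excluded records only; call
    :func:`apply_exclusions` first. Raises
    :class:`~centroquant.errors.UndefinedValueError` if nothing is usable.
    """
    if "excluded" not in records.columns:
        raise DomainError("records lack exclusion flags; run apply_exclusions")
    usable = records[~records["excluded"]]
    n = len(usable)
    if n == 0:
        raise UndefinedValueError("no usable nuclei after exclusions")
    aberrant = int((usable[chromosome] != euploid).sum())
    return aberrant, n, 100.0 * aberrant / n


def chi2_2x2(table: ContingencyTable2x2, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test (1 df) on a 2×2 table.

    Yates continuity correction is off by default and available behind
    ``correction``. Raises on a zero margin.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError(f"zero margin in table {arr.tolist()}")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p)


def percent_change(rate_before: float, rate_after: float) -> float:
    """Relative change of a rate, in percent of the baseline."""
    if rate_before <= 0:
        raise UndefinedValueError("baseline rate must be > 0")
    return 100.0 * (rate_after - rate_before) / rate_before


def instability_report(
    records: pd.DataFrame,
    chromosome: str = "count_ch7",
    group_col: str = "group",
    baseline_group: str = "uninduced",
    euploid: int = 4,
    volume_rule: bool = True,
    correction: bool = False,
) -> dict:
    """Full scoring pipeline: exclusions → per-group rates → χ² → % change.

    Returns a dict with per-group ``(aberrant, usable, rate_pct)``,
    exclusion tallies by reason, the chi-squared statistic and p-value, and
    the percent change of the instability rate relative to
    ``baseline_group``.
    """
    flagged = apply_exclusions(records, volume_rule=volume_rule, group_col=group_col)
    groups = list(flagged[group_col].unique())
    if baseline_group not in groups:
        raise DomainError(f"baseline group {baseline_group!r} not present")
    other = [g for g in groups if g != baseline_group]
    if len(other) != 1:
        raise DomainError(f"need exactly 2 groups, got {groups}")
    comparison_group = other[0]

    per_group = {}
    for g in groups:
        sub = flagged[flagged[group_col] == g]
        ab, n, rate = instability_rate(sub, chromosome, euploid)
        per_group[g] = {"aberrant": ab, "usable": n, "rate_pct": rate}

    t = ContingencyTable2x2(
        a=per_group[comparison_group]["aberrant"],
        b=per_group[comparison_group]["usable"] - per_group[comparison_group]["aberrant"],
        c=per_group[baseline_group]["aberrant"],
        d=per_group[baseline_group]["usable"] - per_group[baseline_group]["aberrant"],
    )
    chi2, p = chi2_2x2(t, correction=correction)
    excl = flagged.loc[flagged["excluded"], "exclude_reason"].value_counts().to_dict()
    return {
        "chromosome": chromosome,
        "groups": per_group,
        "excluded_by_reason": excl,
        "chi2": chi2,
        "p_value": p,
        "percent_change": percent_change(
            per_group[baseline_group]["rate_pct"],
            per_group[comparison_group]["rate_pct"],
        ),
    }
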