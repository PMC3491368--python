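"""ChIP/Input differential statistics for PTM abundance tables.

Each modified form's enrichment in a reader ChIP is the log2 ratio of its
mean relative abundance in the ChIP to that in input (whole-genome)
chromatin; significance per form per ChIP comes from a classical two-
tailed, unpaired (equal-variance) Student's t-test over replicates, with
Benjamini-Hochberg control of the false discovery rate within each ChIP
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fold_change",
    "ttest_two_sample",
    "bh_adjust",
    "build_heatmap_matrix",
]


@dataclass
class FoldChange:
    log2_ratio: float
    flag: str  # "ok" | "pseudocount" | "missing"


def fold_change(
    chip_percent: float, input_percent: float, pseudocount: float = 0.01
) -> FoldChange:
    """log2(ChIP% / Input%); a symmetric pseudocount kicks in only on zeros."""
    if chip_percent < 0 or input_percent < 0:
        raise ValueError("percentages must be non-negative")
    if chip_percent == 0 and input_percent == 0:
        return FoldChange(math.nan, "missing")
    if chip_percent == 0 or input_percent == 0:
        return FoldChange(
            math.log2((chip_percent + pseudocount) / (input_percent + pseudocount)),
            "pseudocount",
        )
    return FoldChange(math.log2(chip_percent / input_percent), "ok")


def ttest_two_sample(
    group_a, group_b, welch: bool = False, log_space: bool = False
) -> float:
    """Two-tailed unpaired Student's t-test p-value (equal variance by default).

    Returns NaN when the pooled variance is zero (flagged undefined).
    ``log_space`` tests log-transformed percentages instead of raw values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if log_space:
        a, b = np.log(a), np.log(b)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return math.nan
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            return math.nan
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; NaNs propagate (they do
    not count toward m).
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        import warnings

        warnings.warn("no finite p-values to adjust")
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[valid] = out
    return q


def build_heatmap_matrix(
    abundance: pd.DataFrame,
    input_sample: str,
    pseudocount: float = 0.01,
    log_space: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(form, ChIP) log2 fold changes with t-test p and BH q values.

    ``abundance`` is a long table with columns form, sample, replicate,
    abundance_pct covering the input sample and one or more ChIPs, each
    with replicate measurements.  Fold changes use replicate means; the
    BH family is all forms within one ChIP comparison.  Cells with a
    missing replicate set are flagged NaN.
    """
    required = {"form", "sample", "replicate", "abundance_pct"}
    if not required.issubset(abundance.columns):
        raise ValueError(f"abundance table must have columns {sorted(required)}")
    samples = [s for s in abundance["sample"].unique() if s != input_sample]
    if input_sample not in set(abundance["sample"]):
        raise ValueError(f"input sample {input_sample!r} absent from table")
    forms = list(dict.fromkeys(abundance["form"]))
    inp = abundance[abundance["sample"] == input_sample]
    fc = pd.DataFrame(index=forms, columns=samples, dtype=float)
    stat_rows = []
    for chip in samples:
        ch = abundance[abundance["sample"] == chip]
        pvals = []
        for form in forms:
            a = ch.loc[ch["form"] == form, "abundance_pct"].to_numpy()
            b = inp.loc[inp["form"] == form, "abundance_pct"].to_numpy()
            if a.size < 2 or b.size < 2:
                fc.loc[form, chip] = np.nan
                pvals.append(np.nan)
                continue
            fc.loc[form, chip] = fold_change(
                float(a.mean()), float(b.mean()), pseudocount
            ).log2_ratio
            pvals.append(ttest_two_sample(a, b, log_space=log_space))
        qvals = bh_adjust(pvals)
        for form, p, q in zip(forms, pvals, qvals):
            stat_rows.append(
                {
                    "form": form,
                    "chip": chip,
                    "log2_fc": fc.loc[form, chip],
                    "p": p,
                    "q": q,
                }
            )
    return fc, pd.DataFrame(stat_rows)
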