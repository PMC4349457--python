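"""ChIP-qPCR and qRT-PCR quantification.

Implements the percent-of-input readout for chromatin immunoprecipitation,
enrichment relative to a reference amplicon (e.g. the cc1/3 central-core
region or act1+), copy-number-corrected relative transcript levels
(delta-delta-Ct normalized over genomic DNA), and replicate statistics with
a Welch t-test significance flag at alpha = 0.05.

All formulas assume exponential amplification with per-cycle efficiency E
(default 2.0, perfect doubling):

    %IP = 100 * f * E**(Ct_input - Ct_IP)

with f the fraction of chromatin set aside as input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

ALPHA = 0.05

_SAMPLES = ("IP", "input", "RT", "gDNA")


@dataclass
class QPCRMeasurement:
    """Ct replicates for one amplicon in one sample type."""

    target: str
    sample: str
    ct: List[float]
    efficiency: float = 2.0
    input_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.sample not in _SAMPLES:
            raise ValueError(f"sample must be one of {_SAMPLES}")
        self.ct = [float(c) for c in self.ct]
        if not self.ct or not all(math.isfinite(c) and c > 0 for c in self.ct):
            raise ValueError("Ct values must be finite and positive")
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError("efficiency must lie in (1, 2.2]")
        if not (0.0 < self.input_fraction <= 1.0):
            raise ValueError("input_fraction must lie in (0, 1]")


@dataclass
class EnrichmentResult:
    """%IP summary for one amplicon, optionally relative to a reference."""

    target: str
    percent_ip: float
    sem: float
    n: int
    values: np.ndarray
    relative: Optional[float] = None
    relative_sem: Optional[float] = None
    p_value: Optional[float] = None
    significant: Optional[bool] = None


def percent_ip(ct_ip, ct_input, efficiency: float = 2.0,
               input_fraction: float = 0.01):
    """Percent of input recovered: 100 * f * E**(Ct_input - Ct_IP).

    Accepts scalars or equal-length arrays (element-wise, replicate-paired).
    """
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    if not (np.all(np.isfinite(ct_ip)) and np.all(np.isfinite(ct_input))):
        raise ValueError("Ct values must be finite")
    if not (1.0 < efficiency <= 2.2):
        raise ValueError("efficiency must lie in (1, 2.2]")
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError("input_fraction must lie in (0, 1]")
    out = 100.0 * input_fraction * efficiency ** (ct_input - ct_ip)
    return float(out) if out.ndim == 0 else out


def summarize_percent_ip(ip: QPCRMeasurement, inp: QPCRMeasurement) -> EnrichmentResult:
    """Replicate-wise %IP with mean and SEM."""
    if ip.target != inp.target:
        raise ValueError("IP and input measurements must share a target")
    vals = percent_ip(np.asarray(ip.ct), np.asarray(inp.ct),
                      efficiency=ip.efficiency, input_fraction=ip.input_fraction)
    vals = np.atleast_1d(vals)
    n = len(vals)
    sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return EnrichmentResult(target=ip.target, percent_ip=float(vals.mean()),
                            sem=sem, n=n, values=vals)


def relative_enrichment(target: EnrichmentResult,
                        reference: EnrichmentResult) -> Tuple[float, float]:
    """Mean %IP ratio target/reference with first-order SEM propagation:

    SEM(r) = r * sqrt((SEM_t/m_t)^2 + (SEM_ref/m_ref)^2)
    """
    if reference.percent_ip <= 0:
        raise ZeroDivisionError("reference enrichment must be positive")
    ratio = target.percent_ip / reference.percent_ip
    rel_var = (target.sem / target.percent_ip) ** 2 if target.percent_ip else 0.0
    rel_var += (reference.sem / reference.percent_ip) ** 2
    return ratio, ratio * math.sqrt(rel_var)


def relative_transcript(ct_rt_target: float, ct_rt_ref: float,
                        ct_gdna_target: float, ct_gdna_ref: float,
                        efficiency: float = 2.0) -> float:
    """Copy-number-corrected relative transcript level (delta-delta-Ct).

    Transcript abundance relative to the reference gene, divided by the
    same ratio measured on genomic DNA so that plasmid/locus copy-number
    differences cancel:

        E**(Ct_rt_ref - Ct_rt_target) / E**(Ct_gdna_ref - Ct_gdna_target)
    """
    cts = (ct_rt_target, ct_rt_ref, ct_gdna_target, ct_gdna_ref)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    rt = efficiency ** (ct_rt_ref - ct_rt_target)
    gdna = efficiency ** (ct_gdna_ref - ct_gdna_target)
    return rt / gdna


@dataclass
class ReplicateStats:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p_value: float
    significant: bool


def replicate_stats(group_a: Sequence[float], group_b: Sequence[float],
                    paired: bool = False) -> ReplicateStats:
    """Two-sided t-test between replicate groups (Welch by default).

    Two zero-variance groups with equal means give p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    sem = lambda x: float(x.std(ddof=1) / math.sqrt(len(x)))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
    elif paired:
        t, p = _stats.ttest_rel(a, b)
    else:
        t, p = _stats.ttest_ind(a, b, equal_var=False)
    return ReplicateStats(mean_a=float(a.mean()), mean_b=float(b.mean()),
                          sem_a=sem(a), sem_b=sem(b), t=float(t),
                          p_value=float(p), significant=bool(p < ALPHA))


def analyze_table(table: pd.DataFrame, reference: Optional[str] = None,
                  efficiency: float = 2.0,
                  input_fraction: float = 0.01) -> pd.DataFrame:
    """Per-target %IP report from a long-format Ct table.

    Expects columns ``target, sample, replicate, ct`` with ``sample`` in
    {IP, input}; replicates are paired by their ``replicate`` index.
    Adds ratios to ``reference`` when given.
    """
    required = {"target", "sample", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    results = {}
    for target, sub in table.groupby("target", sort=False):
        ip = sub[sub["sample"] == "IP"].sort_values("replicate")["ct"].to_numpy()
        inp = sub[sub["sample"] == "input"].sort_values("replicate")["ct"].to_numpy()
        if len(ip) == 0 or len(inp) == 0 or len(ip) != len(inp):
            raise ValueError(f"target {target!r}: need paired IP and input replicates")
        results[target] = summarize_percent_ip(
            QPCRMeasurement(target, "IP", list(ip), efficiency, input_fraction),
            QPCRMeasurement(target, "input", list(inp), efficiency, input_fraction),
        )
    rows = []
    ref = results.get(reference) if reference else None
    if reference and ref is None:
        raise ValueError(f"reference target {reference!r} not in table")
    for target, res in results.items():
        row = {"target": target, "percent_ip": res.percent_ip,
               "sem": res.sem, "n": res.n}
        if ref is not None:
            row["relative"], row["relative_sem"] = relative_enrichment(res, ref)
        rows.append(row)
    return pd.DataFrame(rows)
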