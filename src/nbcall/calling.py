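"""Per-sample variant calling on top of the fitted error model.

For one alteration: the outlier p-value of each sample under the cohort
error model, Benjamini-Hochberg q-values across the cohort, Phred-scaled
QVALs, relative variant strand bias, post-calling filters (annotation
only), technical-replicate intersection, tumour/normal somatic status with
a binomial power check, and the two-feature detectability rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .model import ErrorModelFit, FitConfig, fit_error_model, nb_tail_prob
from .pileup import AlterationKey, SampleCounts, SitePileup

__all__ = [
    "CallerConfig",
    "SampleCall",
    "SiteCalls",
    "compute_pvalues",
    "bh_adjust",
    "phred_qval",
    "compute_rvsb",
    "call_site",
    "apply_post_filters",
    "intersect_replicates",
    "assign_tn_status",
    "predict_detectability",
]

logger = logging.getLogger(__name__)

_MIN_P = np.finfo(float).tiny

FILTER_FLAGS = ("RVSB_FAIL", "PROXIMITY_FAIL", "LOWCONF_CHANGE_FAIL", "SAMPLE_QC_FAIL")
STATUSES = ("SOMATIC", "GERMLINE", "UNKNOWN", "NA")


@dataclass
class CallerConfig:
    qval_threshold: float = 50.0  # germline mode uses 30
    qval_cap: float = 255.0
    rvsb_max: float = 0.85
    proximity_window_bp: int = 5
    proximity_vaf_factor: float = 10.0
    lowconf_changes: frozenset[str] = frozenset()
    lowconf_min_vaf: float = 0.10
    max_raw_calls_per_sample: int = 100
    power_min: float = 0.9
    het_vaf: float = 0.5
    bh_cohort_wide: bool = False  # non-default: pool p-values across sites

    def __post_init__(self) -> None:
        if not (0 <= self.qval_threshold <= self.qval_cap):
            raise ValueError("qval_threshold must lie in [0, qval_cap]")
        if self.proximity_vaf_factor <= 1:
            raise ValueError("proximity_vaf_factor must exceed 1")
        if not (0.5 <= self.rvsb_max <= 1.0):
            raise ValueError("rvsb_max must lie in [0.5, 1]")
        self.lowconf_changes = frozenset(self.lowconf_changes)

    @classmethod
    def germline(cls, **kw) -> "CallerConfig":
        kw.setdefault("qval_threshold", 30.0)
        return cls(**kw)


@dataclass
class SampleCall:
    """Calling outcome for one sample at one alteration."""

    sample_id: str
    p_value: float
    q_value: float
    qval: float
    counts: SampleCounts | None = None
    is_variant: bool = False
    filter_flags: set[str] = field(default_factory=set)
    status: str | None = None
    rvsb: float | None = None  # frozen at call time; strand info may be lost later

    @property
    def vaf(self) -> float | None:
        if self.counts is None or self.counts.dp == 0:
            return None
        return self.counts.ao / self.counts.dp

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags


@dataclass
class SiteCalls:
    """All samples' calls for one alteration, plus the fit that produced them."""

    key: AlterationKey
    fit: ErrorModelFit
    calls: list[SampleCall]
    record_filter: tuple[str, ...] | None = None  # preserved on VCF round trips

    @property
    def variant_calls(self) -> list[SampleCall]:
        return [c for c in self.calls if c.is_variant]

    @property
    def max_qval(self) -> float:
        return max((c.qval for c in self.calls), default=0.0)


# ---------------------------------------------------------------------------


def compute_pvalues(site: SitePileup, fit: ErrorModelFit) -> np.ndarray:
    """Outlier p-value of every sample: P(X >= AO_i) under NB(e*DP_i, sigma).

    DP = 0 gives p = 1; a degenerate fit with e = 0 gives p = 1 at AO = 0
    and the smallest positive float at AO > 0.
    """
    if len(fit.weights) != site.n_samples:
        raise ValueError("fit does not match site: sample count differs")
    ao = np.array([s.ao for s in site.samples], dtype=float)
    dp = np.array([s.dp for s in site.samples], dtype=float)
    p = np.ones(site.n_samples)
    if fit.e_hat == 0.0:
        p[(dp > 0) & (ao > 0)] = _MIN_P
        return p
    usable = dp > 0
    p[usable] = nb_tail_prob(ao[usable], fit.e_hat * dp[usable], fit.sigma_hat)
    return p


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def phred_qval(q: float, cap: float = 255.0) -> float:
    """-10*log10(q), capped; q = 0 maps to the cap."""
    if q <= 0.0:
        return float(cap)
    return float(min(-10.0 * math.log10(q), cap))


def compute_rvsb(c: SampleCounts) -> float | None:
    """Relative variant strand bias in [0.5, 1]; None when undefined.

    max(AO_f*RO_r, AO_r*RO_f) / (AO_f*RO_r + AO_r*RO_f), with RO the
    reference-supporting depth per strand.  Undefined at AO = 0 or when
    both cross products vanish.
    """
    if c.ao == 0:
        return None
    ro_fwd = c.dp_fwd - c.ao_fwd
    ro_rev = c.dp_rev - c.ao_rev
    x = c.ao_fwd * ro_rev
    y = c.ao_rev * ro_fwd
    if x + y == 0:
        return None
    return max(x, y) / (x + y)


def call_site(
    site: SitePileup,
    cfg: CallerConfig | None = None,
    fitcfg: FitConfig | None = None,
    fit: ErrorModelFit | None = None,
) -> SiteCalls:
    """Fit the error model and call every sample at one alteration.

    A pre-computed ``fit`` may be supplied (e.g. when re-scoring); q-values
    are BH-adjusted across the cohort of this alteration.
    """
    cfg = cfg or CallerConfig()
    if fit is None:
        fit = fit_error_model(site, fitcfg)
    p = compute_pvalues(site, fit)
    q = bh_adjust(p)
    calls = []
    for i, counts in enumerate(site.samples):
        qv = phred_qval(q[i], cfg.qval_cap)
        is_var = qv >= cfg.qval_threshold and counts.dp > 0 and counts.ao > 0
        calls.append(
            SampleCall(
                sample_id=counts.sample_id,
                p_value=float(p[i]),
                q_value=float(q[i]),
                qval=qv,
                counts=counts,
                is_variant=is_var,
                rvsb=compute_rvsb(counts),
            )
        )
    return SiteCalls(key=site.key, fit=fit, calls=calls)


# ---------------------------------------------------------------------------
# post-calling filters


def apply_post_filters(sites: Sequence[SiteCalls], cfg: CallerConfig | None = None) -> Sequence[SiteCalls]:
    """Annotate variant calls with filter flags; never removes or rescores.

    Requires ``sites`` sorted by (chrom, pos).  Flags: strand bias at or
    above ``rvsb_max``; a >=``proximity_vaf_factor``-fold higher-VAF called
    variant of another alteration within ``proximity_window_bp`` in the
    same sample; low-confidence base change below ``lowconf_min_vaf``; and
    all calls of samples whose raw variant count exceeds
    ``max_raw_calls_per_sample``.
    """
    cfg = cfg or CallerConfig()
    keys = [(s.key.chrom, s.key.pos) for s in sites]
    if keys != sorted(keys):
        raise ValueError("apply_post_filters requires sites sorted by (chrom, pos)")

    raw_counts: dict[str, int] = {}
    for s in sites:
        for c in s.variant_calls:
            raw_counts[c.sample_id] = raw_counts.get(c.sample_id, 0) + 1
    noisy = {sid for sid, n in raw_counts.items() if n > cfg.max_raw_calls_per_sample}

    for idx, s in enumerate(sites):
        for c in s.calls:
            if not c.is_variant:
                continue
            rvsb = c.rvsb
            if rvsb is not None and rvsb >= cfg.rvsb_max:
                c.filter_flags.add("RVSB_FAIL")
            vaf = c.vaf
            change = s.key.base_change
            if change is not None and change in cfg.lowconf_changes:
                if vaf is not None and vaf < cfg.lowconf_min_vaf:
                    c.filter_flags.add("LOWCONF_CHANGE_FAIL")
            if c.sample_id in noisy:
                c.filter_flags.add("SAMPLE_QC_FAIL")
            if vaf is not None and _has_high_vaf_neighbour(sites, idx, c, vaf, cfg):
                c.filter_flags.add("PROXIMITY_FAIL")
    return sites


def _has_high_vaf_neighbour(
    sites: Sequence[SiteCalls], idx: int, call: SampleCall, vaf: float, cfg: CallerConfig
) -> bool:
    me = sites[idx].key
    for j in range(idx - 1, -1, -1):
        other = sites[j].key
        if other.chrom != me.chrom or me.pos - other.pos > cfg.proximity_window_bp:
            break
        if _neighbour_hit(sites[j], me, call, vaf, cfg):
            return True
    for j in range(idx, len(sites)):
        other = sites[j].key
        if other.chrom != me.chrom or other.pos - me.pos > cfg.proximity_window_bp:
            break
        if sites[j].key == me:
            continue
        if _neighbour_hit(sites[j], me, call, vaf, cfg):
            return True
    return False


def _neighbour_hit(
    other: SiteCalls, me: AlterationKey, call: SampleCall, vaf: float, cfg: CallerConfig
) -> bool:
    if other.key == me:
        return False
    for oc in other.calls:
        if oc.sample_id != call.sample_id or not oc.is_variant:
            continue
        ovaf = oc.vaf
        if ovaf is not None and ovaf >= cfg.proximity_vaf_factor * vaf:
            return True
    return False


# ---------------------------------------------------------------------------
# replicates & tumour-normal


def intersect_replicates(
    a: Iterable[SiteCalls],
    b: Iterable[SiteCalls],
    pairing: Mapping[str, str] | None = None,
) -> set[tuple[AlterationKey, str]]:
    """Validated (alteration, sample) pairs: variant in both libraries.

    ``pairing`` maps sample ids of run ``a`` to ids of run ``b`` (identity
    when omitted); a paired id missing from either run is an error.
    """
    a = list(a)
    b = list(b)
    calls_a = {(s.key, c.sample_id) for s in a for c in s.calls if c.is_variant}
    calls_b = {(s.key, c.sample_id) for s in b for c in s.calls if c.is_variant}
    if pairing is None:
        return calls_a & calls_b
    samples_a = {c.sample_id for s in a for c in s.calls}
    samples_b = {c.sample_id for s in b for c in s.calls}
    for sa, sb in pairing.items():
        if sa not in samples_a:
            raise KeyError(f"pairing sample {sa!r} absent from first replicate")
        if sb not in samples_b:
            raise KeyError(f"pairing sample {sb!r} absent from second replicate")
    fwd = dict(pairing)
    mapped = {(k, fwd[sid]) for k, sid in calls_a if sid in fwd}
    rev = {v: k for k, v in pairing.items()}
    return {(k, rev[sid]) for k, sid in (mapped & calls_b)}


def assign_tn_status(
    tumour: SampleCall,
    normal: SampleCall | None,
    normal_fit: ErrorModelFit | None,
    cfg: CallerConfig | None = None,
    n_samples: int = 1,
) -> str:
    """Somatic/germline status of a tumour variant given its matched normal.

    GERMLINE when the normal itself reaches the calling threshold.
    Otherwise the smallest alternate count ``a*`` that would have been
    called in the normal is found, and the power to observe it under a
    heterozygous binomial is computed: SOMATIC when power is adequate,
    UNKNOWN when the normal is under-covered.
    """
    cfg = cfg or CallerConfig()
    if normal is None or normal.counts is None:
        logger.warning("missing normal counts for tumour %s: status UNKNOWN", tumour.sample_id)
        return "UNKNOWN"
    if normal.qval >= cfg.qval_threshold:
        return "GERMLINE"
    dp_n = normal.counts.dp
    if dp_n == 0:
        return "UNKNOWN"
    e = normal_fit.e_hat if normal_fit is not None else 0.0
    sigma = normal_fit.sigma_hat if normal_fit is not None else 0.0
    target = 10.0 ** (-cfg.qval_threshold / 10.0)
    mu = e * dp_n
    a_star = None
    sd = math.sqrt(mu + sigma * mu * mu) if mu > 0 else 0.0
    a_cap = min(dp_n, int(mu + 100.0 * sd) + 1000)
    for a in range(1, a_cap + 1):
        if nb_tail_prob(a, mu, sigma) * n_samples <= target:
            a_star = a
            break
    if a_star is None:
        return "UNKNOWN"
    power = float(stats.binom.sf(a_star - 1, dp_n, cfg.het_vaf))
    return "SOMATIC" if power >= cfg.power_min else "UNKNOWN"


# ---------------------------------------------------------------------------
# detectability rule


def predict_detectability(vaf: float, dp: float, err: float) -> tuple[bool, float, float]:
    """Two-feature detectability rule.

    Returns ``(detectable, log10(DP*VAF), log10(VAF/err))``; detectable
    requires expected mutant reads above ``10**0.7`` (~5 reads) and a
    VAF-to-error-rate ratio above ``10**0.5`` (~3x).  ``err = 0`` makes the
    second margin infinite.
    """
    if not (0 < vaf <= 1) or dp <= 0 or err < 0:
        raise ValueError("require 0 < vaf <= 1, dp > 0, err >= 0")
    m_reads = math.log10(dp * vaf)
    m_err = math.inf if err == 0 else math.log10(vaf / err)
    return (m_reads > 0.7 and m_err > 0.5), m_reads, m_err
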