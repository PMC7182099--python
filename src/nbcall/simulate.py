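"""Synthetic cohorts with the statistical structure the caller assumes.

Count-level generation (no reads): per alteration, every sample's
alternate count is NB-distributed around ``e * DP``; spiked mutations
replace that draw with a binomial at success probability
``VAF + e * (1 - VAF)``; technical duplicates redraw counts independently
per library.  Spike VAFs follow a log-uniform law ``10**-u`` and are
placed only where the expected mutant read count is adequate.

The single RNG stream is consumed in a fixed, documented order
(sites -> depths -> error draws -> spikes) so that a seed pins the output
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import CallerConfig, SiteCalls, call_site, intersect_replicates
from .model import ErrorModelFit, FitConfig
from .pileup import AlterationKey, SampleCounts, SitePileup

__all__ = [
    "SimulationSpec",
    "TruthRecord",
    "LandscapeBin",
    "SimulatedCohort",
    "simulate_cohort",
    "benchmark_sensitivity",
    "estimate_null_fpr",
    "error_landscape_summary",
    "DEFAULT_ERR_DECADES",
]

_BASES = "ACGT"

#: decade bins used for the error-rate landscape
DEFAULT_ERR_DECADES = ((1e-5, 1e-4), (1e-4, 1e-3), (1e-3, 1e-2), (1e-2, 1e-1))

#: strand-collapsed labels for the 12 substitutions
STRAND_EQUIV = {
    "A>C": "A>C", "T>G": "A>C",
    "A>G": "A>G", "T>C": "A>G",
    "A>T": "A>T", "T>A": "A>T",
    "C>A": "C>A", "G>T": "C>A",
    "C>G": "C>G", "G>C": "C>G",
    "C>T": "C>T", "G>A": "C>T",
}

_TRANSITIONS = {"A>G", "G>A", "C>T", "T>C"}


@dataclass
class SimulationSpec:
    """Generative parameters of one synthetic cohort."""

    n_samples: int = 20
    n_sites: int = 10
    depth: float | tuple[float, float] = 1000  # fixed, or (median, log10-sd)
    e_rate: float | tuple[float, float] = 1e-3  # fixed, or log-uniform range
    sigma: float = 0.1
    n_spikes: int = 0
    spike_vaf: float | None = None  # fixed VAF overrides the log-uniform law
    u_max: float = 4.0
    min_expected_ao: float = 5.0
    duplicates: bool = False
    seed: int = 0
    chrom: str = "sim"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_sites < 1:
            raise ValueError("need at least 1 site")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    key: AlterationKey
    sample_id: str
    true_vaf: float
    replicate_shared: bool = True


@dataclass
class SimulatedCohort:
    pileups: list[SitePileup]
    replicate: list[SitePileup] | None
    truth: list[TruthRecord]

    @property
    def sample_ids(self) -> list[str]:
        return self.pileups[0].sample_ids if self.pileups else []


@dataclass
class LandscapeBin:
    """One error-rate-decade x base-change summary cell."""

    e_range: tuple[float, float]
    base_change: str
    count: int
    total: int

    @property
    def prob(self) -> float | None:
        return self.count / self.total if self.total > 0 else None

    @property
    def collapsed(self) -> str:
        return STRAND_EQUIV.get(self.base_change, self.base_change)

    @property
    def is_transition(self) -> bool:
        return self.base_change in _TRANSITIONS


# ---------------------------------------------------------------------------


def _draw_counts(
    rng: np.random.Generator,
    dp: np.ndarray,
    e: float,
    sigma: float,
) -> np.ndarray:
    """NB error draws, AO_i ~ NB(e*DP_i, sigma) (Poisson when sigma ~ 0)."""
    mu = e * dp
    if e == 0:
        return np.zeros_like(dp)
    if sigma < 1e-8:
        return rng.poisson(mu)
    n = 1.0 / sigma
    p = 1.0 / (1.0 + sigma * mu)
    out = np.zeros(len(dp), dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def _split_strands(rng: np.random.Generator, dp: np.ndarray, ao: np.ndarray, ids):
    """50/50 strand split of DP with binomial noise; AO assigned to strands
    hypergeometrically so per-strand invariants hold by construction."""
    ao = np.minimum(ao, dp)
    dp_fwd = rng.binomial(dp, 0.5)
    dp_rev = dp - dp_fwd
    ao_fwd = rng.hypergeometric(dp_fwd, dp_rev, ao)
    return [
        SampleCounts(
            s,
            dp_fwd=int(dp_fwd[i]),
            dp_rev=int(dp_rev[i]),
            ao_fwd=int(ao_fwd[i]),
            ao_rev=int(ao[i] - ao_fwd[i]),
        )
        for i, s in enumerate(ids)
    ]


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate one cohort (optionally duplicated libraries) plus truth.

    RNG consumption order: site definitions, depths, error-model draws,
    spike placement/draws — fixed so outputs are reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"S{i:04d}" for i in range(spec.n_samples)]

    # 1. sites: positions spaced >= 100 bp apart, random ref/alt, per-site e
    positions = 1 + 100 * np.arange(spec.n_sites)
    refs = rng.choice(list(_BASES), size=spec.n_sites)
    alts = []
    for r in refs:
        others = [b for b in _BASES if b != r]
        alts.append(others[rng.integers(len(others))])
    keys = [
        AlterationKey(spec.chrom, int(positions[i]), str(refs[i]), alts[i])
        for i in range(spec.n_sites)
    ]
    if isinstance(spec.e_rate, tuple):
        lo, hi = np.log10(spec.e_rate[0]), np.log10(spec.e_rate[1])
        e_site = 10.0 ** rng.uniform(lo, hi, size=spec.n_sites)
    else:
        e_site = np.full(spec.n_sites, float(spec.e_rate))

    # 2. depths (per site x sample x library)
    n_lib = 2 if spec.duplicates else 1
    if isinstance(spec.depth, tuple):
        med, lsd = spec.depth
        dps = rng.lognormal(np.log(med), lsd * np.log(10), size=(n_lib, spec.n_sites, spec.n_samples))
        dps = np.maximum(dps.astype(np.int64), 1)
    else:
        dps = np.full((n_lib, spec.n_sites, spec.n_samples), int(spec.depth), dtype=np.int64)

    # 3. error draws
    aos = np.zeros_like(dps)
    for lib in range(n_lib):
        for j in range(spec.n_sites):
            aos[lib, j] = _draw_counts(rng, dps[lib, j], float(e_site[j]), spec.sigma)

    # 4. spikes
    truth: list[TruthRecord] = []
    taken: set[tuple[int, int]] = set()
    for _ in range(spec.n_spikes):
        placed = False
        for _attempt in range(1000):
            if spec.spike_vaf is not None:
                vaf = float(spec.spike_vaf)
            else:
                vaf = 10.0 ** (-rng.uniform(0.0, spec.u_max))
            j = int(rng.integers(spec.n_sites))
            i = int(rng.integers(spec.n_samples))
            if (j, i) in taken:
                continue
            if np.min(dps[:, j, i]) * vaf < spec.min_expected_ao:
                continue
            taken.add((j, i))
            pr = vaf + e_site[j] * (1.0 - vaf)
            for lib in range(n_lib):
                aos[lib, j, i] = rng.binomial(dps[lib, j, i], pr)
            truth.append(TruthRecord(keys[j], ids[i], vaf))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "spike placement failed: no (site, sample) with "
                f"DP*VAF >= {spec.min_expected_ao} after bounded retries"
            )

    libs: list[list[SitePileup]] = []
    for lib in range(n_lib):
        pls = []
        for j in range(spec.n_sites):
            counts = _split_strands(rng, dps[lib, j], np.minimum(aos[lib, j], dps[lib, j]), ids)
            pls.append(SitePileup(keys[j], counts))
        libs.append(pls)

    return SimulatedCohort(
        pileups=libs[0],
        replicate=libs[1] if n_lib == 2 else None,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# benchmarking


def _call_all(
    pileups: Iterable[SitePileup],
    cfg: CallerConfig,
    fitcfg: FitConfig | None,
) -> list[SiteCalls]:
    return [call_site(p, cfg, fitcfg) for p in pileups]


def benchmark_sensitivity(
    cohort: SimulatedCohort,
    cfg: CallerConfig | None = None,
    fitcfg: FitConfig | None = None,
    vaf_bins: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0),
) -> pd.DataFrame:
    """Sensitivity by VAF bin, with duplicate validation when available.

    Returns a table with one row per VAF bin: number of spikes, number
    detected (in both libraries when duplicates were simulated),
    sensitivity, plus cohortwide false-call counts per library and after
    duplicate validation.
    """
    if not cohort.truth:
        raise ValueError("benchmark requires a non-empty truth set")
    cfg = cfg or CallerConfig()
    calls_a = _call_all(cohort.pileups, cfg, fitcfg)
    if cohort.replicate is not None:
        calls_b = _call_all(cohort.replicate, cfg, fitcfg)
        validated = intersect_replicates(calls_a, calls_b)
        called_b = {(s.key, c.sample_id) for s in calls_b for c in s.calls if c.is_variant}
    else:
        validated = {(s.key, c.sample_id) for s in calls_a for c in s.calls if c.is_variant}
        called_b = set()
    called_a = {(s.key, c.sample_id) for s in calls_a for c in s.calls if c.is_variant}

    true_pairs = {(t.key, t.sample_id): t.true_vaf for t in cohort.truth}
    fp_single = len(called_a - set(true_pairs))
    fp_validated = len(validated - set(true_pairs))

    edges = np.asarray(vaf_bins)
    rows = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        in_bin = [pair for pair, v in true_pairs.items() if lo <= v < hi]
        det = sum(1 for pair in in_bin if pair in validated)
        rows.append(
            {
                "vaf_lo": lo,
                "vaf_hi": hi,
                "n_spikes": len(in_bin),
                "n_detected": det,
                "sensitivity": det / len(in_bin) if in_bin else np.nan,
                "fp_single_library": fp_single,
                "fp_validated": fp_validated,
            }
        )
    return pd.DataFrame(rows)


def estimate_null_fpr(
    spec: SimulationSpec,
    cfg: CallerConfig | None = None,
    fitcfg: FitConfig | None = None,
    thresholds: Sequence[float] = (20, 30, 40, 50, 60, 70),
    n_reps: int = 1,
) -> pd.DataFrame:
    """False-call counts on spike-free cohorts as a function of threshold.

    One row per QVAL threshold: total false calls over ``n_reps``
    replicate cohorts, rate per (alteration x sample) test, and the
    binomial Monte-Carlo standard error of that rate.
    """
    if spec.n_spikes != 0:
        raise ValueError("null FPR estimation requires n_spikes = 0")
    cfg = cfg or CallerConfig()
    qvals: list[float] = []
    n_tests = 0
    for rep in range(n_reps):
        rspec = SimulationSpec(**{**spec.__dict__, "seed": spec.seed + rep})
        cohort = simulate_cohort(rspec)
        for pileup in cohort.pileups:
            sc = call_site(pileup, cfg, fitcfg)
            qvals.extend(
                c.qval for c in sc.calls if c.counts is not None and c.counts.ao > 0 and c.counts.dp > 0
            )
            n_tests += len(sc.calls)
    qarr = np.asarray(qvals)
    rows = []
    for thr in thresholds:
        fp = int(np.sum(qarr >= thr))
        rate = fp / n_tests if n_tests else np.nan
        se = np.sqrt(rate * (1 - rate) / n_tests) if n_tests else np.nan
        rows.append({"threshold": thr, "fp": fp, "n_tests": n_tests, "rate": rate, "se": se})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error-rate landscape


def error_landscape_summary(
    fits: Mapping[AlterationKey, ErrorModelFit],
    ranges: Sequence[tuple[float, float]] = DEFAULT_ERR_DECADES,
    reference_context: Mapping[str, str] | None = None,
) -> list[LandscapeBin]:
    """Bin positive SNV error-rate estimates by decade x base change.

    Within each decade the per-base-change probabilities sum to one.
    Zero estimates are not binned (callers report them separately).
    ``reference_context`` (chrom -> sequence) is accepted for indel
    homopolymer stratification by downstream tooling; indel keys are
    skipped here.
    """
    bins: list[LandscapeBin] = []
    snv = [(k, f) for k, f in fits.items() if k.alt_class == "SNV" and f.e_hat > 0]
    for lo, hi in ranges:
        in_range = [k.base_change for k, f in snv if lo <= f.e_hat < hi]
        total = len(in_range)
        for change in sorted(STRAND_EQUIV):
            bins.append(
                LandscapeBin(
                    e_range=(lo, hi),
                    base_change=change,
                    count=sum(1 for c in in_range if c == change),
                    total=total,
                )
            )
    return bins


def landscape_to_frame(bins: Iterable[LandscapeBin]) -> pd.DataFrame:
    rows = [
        {
            "e_lo": b.e_range[0],
            "e_hi": b.e_range[1],
            "base_change": b.base_change,
            "collapsed": b.collapsed,
            "transition": b.is_transition,
            "count": b.count,
            "total": b.total,
            "prob": b.prob if b.prob is not None else np.nan,
        }
        for b in bins
    ]
    return pd.DataFrame(rows)
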