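"""Synthetic twin-quartet study generator.

Each family consists of two parents, each carrying private CNVs plus draws
from a shared population pool, and monozygotic twins whose (identical) true
genome is the union of the CNVs each parent transmits with probability 1/2.
De novo CNVs are not simulated — they contribute a negligible share of the
CNV burden — so every true twin call is inherited by construction, and any
Mendelian inconsistency in the observed data comes from the virtual
callers' error models.

A virtual caller observes a true genome through a :class:`CallerProfile`:
per-CNV miss probability (false negatives), a Poisson count of uniformly
placed false positives, Gaussian breakpoint jitter, multiplicative size
bias, and fragmentation (one CNV emitted as two sub-calls separated by a
sub-5-kb gap, which downstream gap-merging can heal).  Every emitted call
carries ground-truth labels, so each downstream metric can be checked
against what the simulator actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .types import CallSet, CNVCall, Pedigree, Quartet, Status

#: default synthetic genome: five chromosomes, 200 Mb total — a scaled-down
#: stand-in for a mammalian genome that keeps every analysis fast.
DEFAULT_CHROM_LENGTHS = {
    "1": 60_000_000,
    "2": 50_000_000,
    "3": 40_000_000,
    "4": 30_000_000,
    "5": 20_000_000,
}


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one virtual caller.

    fp_rate is the expected number of false calls per sample (Poisson mean);
    fn_prob the per-true-CNV miss probability; jitter_sd the Gaussian
    breakpoint noise in bp; frag_prob the probability a detected CNV is
    emitted as two fragments with an internal sub-5-kb gap; size_bias a
    multiplicative distortion of the emitted size (1 = unbiased).
    """

    name: str
    fp_rate: float = 0.0
    fn_prob: float = 0.0
    jitter_sd: float = 0.0
    frag_prob: float = 0.0
    size_bias: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.fn_prob <= 1 or not 0 <= self.frag_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0 or self.size_bias <= 0:
            raise ValueError("fp_rate/jitter_sd must be >= 0 and size_bias > 0")


def zero_noise_profile(name: str = "exact") -> CallerProfile:
    return CallerProfile(name=name)


#: four virtual callers echoing the behaviours the study design probes:
#: a clean read-depth caller with mild size overestimation, a clean hybrid,
#: a permissive paired-end caller with many false positives and sloppy
#: breakpoints, and a heavily fragmenting caller.
DEFAULT_PROFILES = (
    CallerProfile("rd_clean", fp_rate=5, fn_prob=0.03, jitter_sd=150, frag_prob=0.02, size_bias=1.1),
    CallerProfile("hybrid_clean", fp_rate=8, fn_prob=0.05, jitter_sd=100, frag_prob=0.02),
    CallerProfile("pem_noisy", fp_rate=60, fn_prob=0.15, jitter_sd=400, frag_prob=0.05, size_bias=0.8),
    CallerProfile("fragmenting", fp_rate=25, fn_prob=0.10, jitter_sd=250, frag_prob=0.55),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs; the defaults mirror a 9-quartet twin study with
    four virtual callers on a 200 Mb synthetic genome."""

    n_families: int = 9
    n_cnvs_per_parent: int = 60
    cnv_size_log_mean: float = float(np.log(8_000))  # log-bp; median 8 kb
    cnv_size_log_sd: float = 0.9
    gain_fraction: float = 0.4
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    transmission_prob: float = 0.5
    population_cnv_pool_size: int = 40
    carrier_frequency: float = 0.25
    min_separation: int = 10_000  # keeps distinct true CNVs unmergeable at 5 kb
    profiles: tuple = DEFAULT_PROFILES
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in [
            (self.gain_fraction, "gain_fraction"),
            (self.transmission_prob, "transmission_prob"),
            (self.carrier_frequency, "carrier_frequency"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_families < 1 or self.n_cnvs_per_parent < 0:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class TrueCNV:
    """One planted CNV with a stable identity for truth tracking."""

    cnv_id: str
    chrom: str
    start: int
    end: int
    status: Status


@dataclass
class TruthGenomes:
    """True (noise-free) genomes per sample plus the pedigree wiring."""

    pedigree: Pedigree
    genomes: dict[str, tuple[TrueCNV, ...]]  # sample_id -> planted CNVs

    def true_callset(self, sample_id: str, source: str = "truth") -> CallSet:
        return CallSet.from_iter(
            [
                CNVCall(t.chrom, t.start, t.end, t.status, sample_id=sample_id, source=source)
                for t in self.genomes[sample_id]
            ],
            sample_id=sample_id,
            source=source,
        )


@dataclass
class StudyData:
    """A complete simulated study: observed calls per source per sample,
    pedigree, truth genomes, and a per-emitted-call truth table."""

    calls: dict[str, dict[str, CallSet]]  # source -> sample -> CallSet
    pedigree: Pedigree
    truth: TruthGenomes
    truth_table: pd.DataFrame


TRUTH_COLUMNS = [
    "sample_id", "source", "chrom", "start", "end", "status",
    "is_true", "true_id", "inherited",
]


def _draw_size(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    return max(1_000, int(round(rng.lognormal(cfg.cnv_size_log_mean, cfg.cnv_size_log_sd))))


def _place_nonoverlapping(
    n: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    id_prefix: str,
    max_tries: int = 200,
) -> list[TrueCNV]:
    """Place ``n`` CNVs uniformly, rejecting positions within
    ``min_separation`` of anything already placed in ``occupied`` (which is
    updated in place)."""
    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: list[TrueCNV] = []
    for k in range(n):
        size = _draw_size(cfg, rng)
        for attempt in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            length = cfg.chrom_lengths[chrom]
            if length <= size:
                continue
            start = int(rng.integers(0, length - size))
            end = start + size
            sep = cfg.min_separation
            if all(
                end + sep <= s or start >= e + sep for s, e in occupied.get(chrom, [])
            ):
                occupied.setdefault(chrom, []).append((start, end))
                status = Status.GAIN if rng.random() < cfg.gain_fraction else Status.LOSS
                placed.append(TrueCNV(f"{id_prefix}:{k}", chrom, start, end, status))
                break
        else:
            raise RuntimeError(
                f"could not place a {size} bp CNV after {max_tries} tries; "
                "genome too small for the requested density"
            )
    return placed


def simulate_truth(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> TruthGenomes:
    """Generate true genomes for every quartet member.

    Parents carry private CNVs plus population-pool CNVs (each parent is an
    independent carrier of each pool CNV with ``carrier_frequency``); each
    parental CNV transmits to the child with ``transmission_prob``; twin 2's
    genome is an exact copy of twin 1's.  Deterministic given the config
    seed (or an explicit rng).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    # the population pool is shared across families: place it once
    pool_occupied: dict[str, list[tuple[int, int]]] = {}
    pool = _place_nonoverlapping(
        cfg.population_cnv_pool_size, cfg, rng, pool_occupied, "pool"
    )
    families: list[Quartet] = []
    genomes: dict[str, tuple[TrueCNV, ...]] = {}
    for f in range(cfg.n_families):
        fam_id = f"F{f + 1}"
        quartet = Quartet(
            family_id=fam_id,
            twin1=f"{fam_id}-T1",
            twin2=f"{fam_id}-T2",
            parent1=f"{fam_id}-P1",
            parent2=f"{fam_id}-P2",
        )
        families.append(quartet)
        child: list[TrueCNV] = []
        for parent in (quartet.parent1, quartet.parent2):
            # carried pool CNVs first, then private ones placed around them
            occupied: dict[str, list[tuple[int, int]]] = {}
            carried = [p for p in pool if rng.random() < cfg.carrier_frequency]
            for p in carried:
                occupied.setdefault(p.chrom, []).append((p.start, p.end))
            private = _place_nonoverlapping(
                cfg.n_cnvs_per_parent, cfg, rng, occupied, f"{parent}"
            )
            parental = sorted(carried + private, key=lambda t: (t.chrom, t.start))
            genomes[parent] = tuple(parental)
            child.extend(t for t in parental if rng.random() < cfg.transmission_prob)
        child_sorted = tuple(sorted(child, key=lambda t: (t.chrom, t.start)))
        genomes[quartet.twin1] = child_sorted
        genomes[quartet.twin2] = child_sorted
    return TruthGenomes(pedigree=Pedigree(families=tuple(families)), genomes=genomes)


def observe(
    truth: TruthGenomes,
    sample_id: str,
    profile: CallerProfile,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[CallSet, list[dict]]:
    """One virtual caller's view of one sample's true genome.

    Returns the emitted CallSet plus its truth-table rows.  With a
    zero-noise profile the observation equals the true genome exactly.
    """
    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    inherited_ids = _inherited_ids(truth, sample_id)
    emitted: list[CNVCall] = []
    rows: list[dict] = []

    def emit(chrom: str, start: int, end: int, status: Status, is_true: bool, true_id: str):
        length = cfg.chrom_lengths[chrom]
        start = max(0, min(start, length - 1))
        end = max(start + 1, min(end, length))
        call = CNVCall(chrom, start, end, status, sample_id=sample_id, source=profile.name)
        emitted.append(call)
        rows.append(
            {
                "sample_id": sample_id,
                "source": profile.name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "status": status.value,
                "is_true": is_true,
                "true_id": true_id,
                "inherited": is_true and true_id in inherited_ids,
            }
        )

    for t in truth.genomes[sample_id]:
        if rng.random() < profile.fn_prob:
            continue
        center = (t.start + t.end) / 2
        size = (t.end - t.start) * profile.size_bias
        start = center - size / 2 + rng.normal(0, profile.jitter_sd)
        end = center + size / 2 + rng.normal(0, profile.jitter_sd)
        start, end = int(round(start)), int(round(end))
        if end <= start:
            end = start + 1
        if rng.random() < profile.frag_prob and (end - start) > 3_000:
            # two fragments with an internal gap < 5 kb, healable by merging
            gap = int(rng.integers(200, 4_800))
            gap = min(gap, (end - start) // 3)
            cut = int(rng.integers(start + (end - start) // 4, end - (end - start) // 4))
            emit(t.chrom, start, max(start + 1, cut - gap // 2), t.status, True, t.cnv_id)
            emit(t.chrom, min(end - 1, cut + gap // 2), end, t.status, True, t.cnv_id)
        else:
            emit(t.chrom, start, end, t.status, True, t.cnv_id)

    for _ in range(rng.poisson(profile.fp_rate)):
        size = _draw_size(cfg, rng)
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = cfg.chrom_lengths[chrom]
        if length <= size:
            size = length // 2
        start = int(rng.integers(0, length - size))
        status = Status.GAIN if rng.random() < cfg.gain_fraction else Status.LOSS
        emit(chrom, start, start + size, status, False, "")

    return (
        CallSet.from_iter(emitted, sample_id=sample_id, source=profile.name),
        rows,
    )


def _inherited_ids(truth: TruthGenomes, sample_id: str) -> set[str]:
    """True-CNV ids that satisfy the Mendelian/twin criterion for a twin
    sample (trivially all of them here, since de novo CNVs are not
    simulated); parents get an empty set — the inherited flag is a
    twin-level notion."""
    fam = truth.pedigree.family_of(sample_id)
    if sample_id not in (fam.twin1, fam.twin2):
        return set()
    twin_ids = {t.cnv_id for t in truth.genomes[fam.twin1]}
    parent_ids = {t.cnv_id for t in truth.genomes[fam.parent1]} | {
        t.cnv_id for t in truth.genomes[fam.parent2]
    }
    return twin_ids & parent_ids


def expected_inherited_rate(
    n_cnvs_per_parent: int,
    fn_prob: float,
    fp_rate: float,
    transmission_prob: float = 0.5,
) -> float:
    """Exact expected per-family inherited rate under a pure FN/FP error
    model (no jitter, no fragmentation, no population pool).

    Derivation: the twins share T true CNVs, T ~ Binomial(2n, τ) over the
    parents' private CNVs.  With per-call miss probability β, each true CNV
    is observed in neither twin (prob β²), one twin (2β(1-β)) or both
    ((1-β)²); a both-twin CNV is validated when its origin parent also
    observes it (prob 1-β).  Writing m and k for the one-twin and both-twin
    counts and P ~ Poisson(2F) for the pooled false-positive count (false
    calls essentially never match anything), the twins' call total is
    N1+N2 = m + 2k + P while the validated total is 2·Binomial(k, 1-β), so

        E[rate] = E[ 2k(1-β) / (m + 2k + P) ],

    the expectation running over (T, m, k, P) and conditioned on a nonzero
    denominator (families whose twins call nothing are skipped, matching
    the pipeline).  Computed by direct summation over the discrete grid.
    """
    beta, tau = fn_prob, transmission_prob
    n2 = 2 * n_cnvs_per_parent
    t_grid = np.arange(n2 + 1)
    p_t = _binom_pmf(t_grid, n2, tau)

    lam = 2 * fp_rate
    p_max = int(np.ceil(lam + 12 * np.sqrt(lam) + 10))
    p_grid = np.arange(p_max + 1)
    pois = np.exp(p_grid * np.log(lam) - lam - _gammaln(p_grid + 1)) if lam > 0 else None
    if pois is None:
        pois = np.zeros(p_max + 1)
        pois[0] = 1.0

    q_none, q_one, q_both = beta**2, 2 * beta * (1 - beta), (1 - beta) ** 2
    num = 0.0
    mass = 0.0  # probability of a defined (nonzero-denominator) family
    for t, pt in zip(t_grid, p_t):
        if pt < 1e-300:
            continue
        m_grid = np.arange(t + 1)
        for k in range(t + 1):
            m_max = t - k
            m = m_grid[: m_max + 1]
            # multinomial over (none, one twin, both twins)
            p_mk = (
                np.exp(
                    _gammaln(t + 1)
                    - _gammaln(k + 1)
                    - _gammaln(m + 1)
                    - _gammaln(t - k - m + 1)
                )
                * q_both**k
                * q_one**m
                * q_none ** (t - k - m)
            )
            denom = m[:, None] + 2 * k + p_grid[None, :]
            defined = denom > 0
            w = p_mk[:, None] * pois[None, :]
            ratio = np.where(defined, 2 * k * (1 - beta) / np.where(defined, denom, 1), 0.0)
            num += pt * float((w * ratio).sum())
            mass += pt * float((w * defined).sum())
    return num / mass


def _binom_pmf(k, n, p):
    from scipy.stats import binom

    return binom.pmf(k, n, p)


def _gammaln(x):
    from scipy.special import gammaln

    return gammaln(x)


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Full synthetic study: truth genomes observed through every caller
    profile, with pedigree and truth table.  Reproducible from cfg.seed."""
    root = np.random.SeedSequence(cfg.seed)
    truth_ss, obs_ss = root.spawn(2)
    truth = simulate_truth(cfg, np.random.default_rng(truth_ss))
    calls: dict[str, dict[str, CallSet]] = {}
    all_rows: list[dict] = []
    obs_children = obs_ss.spawn(len(cfg.profiles))
    for profile, child_ss in zip(cfg.profiles, obs_children):
        rng = np.random.default_rng(child_ss)
        per_sample: dict[str, CallSet] = {}
        for sid in truth.pedigree.samples:
            cs, rows = observe(truth, sid, profile, cfg, rng)
            per_sample[sid] = cs
            all_rows.extend(rows)
        calls[profile.name] = per_sample
    truth_table = pd.DataFrame(all_rows, columns=TRUTH_COLUMNS)
    return StudyData(calls=calls, pedigree=truth.pedigree, truth=truth, truth_table=truth_table)
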