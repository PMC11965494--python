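"""Synthetic data generators with the statistical structure the analysis
assumes: rhythmic absolute mRNA (ln-cosine, log-normal noise, reduced
amplitude in constant light), PBM E-score mixtures generated from a known
energy matrix, promoters with planted binding sites and mutated haplotypes,
and ln-linear luminescence calibration curves with the protocol's spike
series (0, 1e2 ... 1e6 monomers per cell).

Every generator is seed-deterministic and emits its ground truth alongside
the data, so each downstream stage has a recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import BASES, EnergyMatrix, revcomp
from .regimes import LightRegime
from .simple_model import RnaTimeseries

SPIKE_LEVELS = (0.0, 1e2, 1e3, 1e4, 1e5, 1e6)   # monomers per cell


@dataclass(frozen=True)
class RhythmSpec:
    """A rhythmic transcript in ln-space: cosine between ln-trough and
    ln-peak, with the amplitude damped by ``ld_ll_amplitude_ratio`` under
    constant light (mRNA rhythms flatten in LL)."""

    gene_id: str
    period: float = 24.0               # h
    peak_phase: float = 1.0            # ZT h
    log_peak: float = np.log(100.0)    # ln(copies/cell)
    log_trough: float = np.log(1.0)
    ld_ll_amplitude_ratio: float = 0.5
    noise_sd: float = 0.1              # ln-units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.log_peak < self.log_trough:
            raise ValueError("log_peak must be >= log_trough")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_rna_timeseries(spec: RhythmSpec, regime: LightRegime,
                       sampling_interval: float = 2.0) -> RnaTimeseries:
    """Sample an ln-cosine rhythm over the regime; strictly positive
    copies/cell, byte-identical for identical seeds."""
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    n = regime.duration / sampling_interval
    if abs(n - round(n)) > 1e-9:
        raise ValueError("sampling_interval must divide the regime duration")
    t = regime.t0 + sampling_interval * np.arange(int(round(n)) + 1)
    mid = 0.5 * (spec.log_peak + spec.log_trough)
    amp = 0.5 * (spec.log_peak - spec.log_trough)
    ll0 = regime.ll_start()
    amps = np.full(t.shape, amp)
    if ll0 is not None:
        amps[t >= ll0] *= spec.ld_ll_amplitude_ratio
    ln_m = mid + amps * np.cos(2 * np.pi * (t - spec.peak_phase) / spec.period)
    rng = np.random.default_rng(spec.seed)
    ln_m = ln_m + rng.normal(0.0, spec.noise_sd, size=t.shape)
    light = np.array([regime.light_at(min(x, regime.t1)) for x in t])
    return RnaTimeseries(spec.gene_id, t, np.exp(ln_m), light)


@dataclass(frozen=True)
class PbmTruth:
    """Ground truth for a synthetic PBM: a known energy matrix, the fraction
    of 8-mers that are bound (the lowest-energy fraction), and the E-score
    error model of each class.  The default unbound mean of 0.25 reproduces
    the mutated-probe artefact (a "non-binding" sequence scoring ~0.25)."""

    matrix: EnergyMatrix
    frac_bound: float = 0.02
    bound_noise_sd: float = 0.05
    unbound_noise_sd: float = 0.05
    n_kmers: int = 3000
    seed: int = 0
    bound_mean: float = 0.42
    unbound_mean: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_bound <= 1.0:
            raise ValueError("frac_bound must be in [0, 1]")
        if self.n_kmers > 4 ** 8:
            raise ValueError("n_kmers exceeds the 8-mer universe")
        if self.n_kmers < 1:
            raise ValueError("n_kmers must be positive")


def _int_to_kmer(i: int, k: int = 8) -> str:
    return "".join(BASES[(i >> (2 * (k - 1 - j))) & 3] for j in range(k))


def gen_pbm_dataset(truth: PbmTruth) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic PBM table (kmer, escore) plus true bound labels.

    Distinct 8-mers are sampled without replacement, with reverse-complement
    duplicates collapsed (each pair contributes at most one orientation, the
    one drawn).  The lowest-energy ``frac_bound`` of the sample is bound;
    E-scores are Gaussian around each class mean, so the two populations
    overlap at the default noise levels.
    """
    rng = np.random.default_rng(truth.seed)
    chosen: dict[str, None] = {}
    seen_pairs: set[str] = set()
    while len(chosen) < truth.n_kmers:
        draw = rng.integers(0, 4 ** 8, size=2 * (truth.n_kmers - len(chosen)))
        for i in draw:
            kmer = _int_to_kmer(int(i))
            key = min(kmer, revcomp(kmer))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            chosen[kmer] = None
            if len(chosen) == truth.n_kmers:
                break
    kmers = list(chosen)
    energies = np.array([truth.matrix.energy(k) for k in kmers])
    n_bound = int(round(truth.frac_bound * len(kmers)))
    order = np.argsort(energies, kind="stable")
    labels = np.zeros(len(kmers), dtype=bool)
    labels[order[:n_bound]] = True
    mean = np.where(labels, truth.bound_mean, truth.unbound_mean)
    sd = np.where(labels, truth.bound_noise_sd, truth.unbound_noise_sd)
    escore = rng.normal(mean, sd)
    pbm = pd.DataFrame({"kmer": kmers, "escore": escore})
    return pbm, pd.Series(labels, index=kmers, name="bound")


def gen_promoter_set(length: int, planted_sites: list[tuple[str, int, str]],
                     n_haplotypes: int = 1, mutation_rate: float = 0.0,
                     seed: int = 0) -> list[SeqRecord]:
    """Random promoters with planted binding sites.

    ``planted_sites`` is a list of (8-mer, position, strand); minus-strand
    sites are planted as their reverse complement.  Haplotype 0 is the
    reference and carries every planted site verbatim; later haplotypes are
    mutated at ``mutation_rate`` per bp.
    """
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    occupied: list[tuple[int, int]] = []
    for kmer, pos, _strand in planted_sites:
        if pos < 0 or pos + len(kmer) > length:
            raise ValueError(f"planted site at {pos} does not fit in {length} bp")
        for a, b in occupied:
            if pos < b and a < pos + len(kmer):
                raise ValueError(f"overlapping planted sites at position {pos}")
        occupied.append((pos, pos + len(kmer)))
    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, 4, size=length)
    ref = np.array([BASES[i] for i in base_idx])
    for kmer, pos, strand in planted_sites:
        insert = kmer if strand == "+" else revcomp(kmer)
        ref[pos:pos + len(kmer)] = list(insert)
    records = [SeqRecord(Seq("".join(ref)), id="hap0", description="reference")]
    for h in range(1, n_haplotypes):
        hap = ref.copy()
        if mutation_rate > 0:
            hits = np.nonzero(rng.random(length) < mutation_rate)[0]
            for i in hits:
                alt = [b for b in BASES if b != hap[i]]
                hap[i] = alt[rng.integers(0, 3)]
        records.append(SeqRecord(Seq("".join(hap)), id=f"hap{h}",
                                 description="mutated haplotype"))
    return records


def random_energy_matrix(seed: int = 0, scale: float = 2.0) -> EnergyMatrix:
    """A non-degenerate gauged matrix with one clear consensus base per
    position, energy penalties of order ``scale`` for mismatches."""
    rng = np.random.default_rng(seed)
    e = rng.uniform(0.5, 1.0, size=(8, 4)) * scale
    for i in range(8):
        e[i, rng.integers(0, 4)] = 0.0
    return EnergyMatrix(e).gauged()


def gen_calibration_curve(true_intercept: float, true_slope: float,
                          spike_levels=SPIKE_LEVELS, noise_sd: float = 0.0,
                          replicates: int = 4, seed: int = 0,
                          background_lum: float = 100.0) -> pd.DataFrame:
    """Synthetic spike-in standard curve.

    Positive-spike wells read ``background + exp(intercept + slope*ln(copies)
    + eps)``; zero-spike wells are background-only (log-normal around the
    background), matching the protocol's six-level spike series and its
    ln-linear regression after background subtraction.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(l < 0 for l in spike_levels):
        raise ValueError("spike levels must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for level in spike_levels:
        for rep in range(replicates):
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            if level == 0:
                lum = background_lum * np.exp(eps)
            else:
                lum = background_lum + np.exp(true_intercept
                                              + true_slope * np.log(level) + eps)
            rows.append({"well": f"W{well:02d}", "replicate": rep,
                         "spike_copies_per_cell": float(level),
                         "luminescence": float(lum)})
            well += 1
    return pd.DataFrame(rows)
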