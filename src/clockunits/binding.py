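"""PBM-to-Kd pipeline: energy-matrix inference, calibration, promoter scans.

The protein-binding microarray (PBM) reports an enrichment score (E-score,
roughly in [-0.5, 0.5]) for every 8-mer.  The score distribution is a
mixture of bound and unbound probe populations that overlap, so instead of
an arbitrary E-score cut-off an error-model-averaging (EMA) deconvolution is
used: an additive binding-energy matrix (8 positions x 4 bases, lower energy
= tighter binding) parameterises the probability that an 8-mer is bound, and
the binned E-score distribution of each class is modelled with its own error
distribution.  Expectation-maximisation alternates posterior class
assignment with (a) Gaussian error-model updates per class and (b) a
weighted logistic fit of the energy matrix.

A handful of sequences with biophysical affinity measurements (SPR/EMSA)
anchor a linear E-score -> Kd (nM) calibration, which converts promoter
scans into per-site and total dissociation constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .clock_model import ClockModel, add_driven_species
from .units import QuantConstants, conc_to_copies

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
K = 8


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement;
    PBM E-scores do not distinguish strands."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class EnergyMatrix:
    """Additive binding energies, 8 positions x 4 bases (A, C, G, T).

    Lower energy = tighter binding.  The gauge fixes the per-position minimum
    at 0, so the consensus (minimum-energy) sequence has total energy 0;
    adding a constant to all entries of one position changes no relative
    energy or posterior.
    """

    energies: np.ndarray
    reference: str = "per-position minimum fixed to 0"

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (K, 4):
            raise ValueError(f"energy matrix must be {K}x4, got {self.energies.shape}")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energy matrix entries must be finite")

    def gauged(self) -> "EnergyMatrix":
        return EnergyMatrix(self.energies - self.energies.min(axis=1, keepdims=True),
                            self.reference)

    def energy(self, kmer: str) -> float:
        if len(kmer) != K:
            raise ValueError(f"need an {K}-mer, got {kmer!r}")
        return float(sum(self.energies[i, _BASE_IDX[b]] for i, b in enumerate(kmer)))

    def canonical_energy(self, kmer: str) -> tuple[float, str]:
        """Minimum energy over the two orientations; returns (energy, strand)."""
        e_fwd = self.energy(kmer)
        e_rev = self.energy(revcomp(kmer))
        return (e_fwd, "+") if e_fwd <= e_rev else (e_rev, "-")

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmin(self.energies, axis=1))


def one_hot(kmers: list[str]) -> np.ndarray:
    x = np.zeros((len(kmers), K * 4))
    for r, kmer in enumerate(kmers):
        for i, b in enumerate(kmer):
            x[r, i * 4 + _BASE_IDX[b]] = 1.0
    return x


@dataclass
class EmaResult:
    """Fitted EMA deconvolution of a PBM dataset."""

    matrix: EnergyMatrix
    intercept: float                      # bound prior: sigmoid(intercept - E)
    posterior_bound: pd.Series            # per dataset 8-mer
    bins: np.ndarray
    class_params: dict                    # mu/sd of bound and unbound E-scores
    escore_slope: float                   # linear energy -> predicted E-score
    escore_intercept: float
    fit_log: list = field(default_factory=list)

    def prior_bound(self, energy: float | np.ndarray) -> float | np.ndarray:
        z = self.intercept - np.asarray(energy, dtype=float)
        out = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return float(out) if out.ndim == 0 else out

    def predict_escore(self, energy: float | np.ndarray):
        return self.escore_intercept + self.escore_slope * np.asarray(energy, float)


def _binned_class_probs(edges: np.ndarray, mu: float, sd: float) -> np.ndarray:
    lo = np.concatenate(([-np.inf], edges[1:-1]))
    hi = np.concatenate((edges[1:-1], [np.inf]))
    p = stats.norm.cdf(hi, mu, sd) - stats.norm.cdf(lo, mu, sd)
    p = np.maximum(p, 1e-12)
    return p / p.sum()


def ema_infer(pbm: pd.DataFrame, n_bins: int = 20,
              init: EnergyMatrix | None = None, seed: int = 0,
              max_iter: int = 200, tol: float = 1e-9,
              l2_c: float = 100.0) -> EmaResult:
    """Infer the binding-energy matrix and bound/unbound deconvolution.

    ``pbm`` needs columns ``kmer`` (8-mers, one orientation each) and
    ``escore``.  Returns the gauged matrix maximising the error-model-
    averaged likelihood of the binned E-scores under the additive energy
    model, plus per-8-mer bound posteriors.  Deterministic for a given seed.
    """
    kmers = pbm["kmer"].astype(str).tolist()
    scores = pbm["escore"].to_numpy(dtype=float)
    if len(kmers) != len(set(kmers)):
        raise ValueError("duplicate k-mers in PBM table")
    if len(kmers) < 33:
        raise ValueError("too few distinct 8-mers to constrain 24 free "
                         "energies (need >= 33)")
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        raise ValueError("degenerate E-score distribution (single bin)")
    bin_idx = np.clip(np.searchsorted(edges[1:-1], scores, side="right"),
                      0, edges.size - 2)

    X = one_hot(kmers)
    rng = np.random.default_rng(seed)
    if init is not None:
        e0 = np.array([init.energy(k) for k in kmers])
        post = (e0 <= np.median(e0)).astype(float)
    else:
        post = (scores > np.median(scores)).astype(float)
        post = np.clip(post + rng.normal(0, 1e-3, post.size), 0.0, 1.0)

    clf = LogisticRegression(C=l2_c, solver="lbfgs", max_iter=500)
    Xd = np.vstack([X, X])
    yd = np.concatenate([np.ones(len(kmers)), np.zeros(len(kmers))])
    ll_prev, fit_log = -np.inf, []
    w = np.zeros(K * 4)
    a = 0.0
    for it in range(max_iter):
        # M-step, error models (raw scores; binning enters the likelihood)
        w1, w0 = post, 1.0 - post
        mu1 = float(np.average(scores, weights=np.maximum(w1, 1e-9)))
        mu0 = float(np.average(scores, weights=np.maximum(w0, 1e-9)))
        sd1 = float(np.sqrt(np.average((scores - mu1) ** 2,
                                       weights=np.maximum(w1, 1e-9))))
        sd0 = float(np.sqrt(np.average((scores - mu0) ** 2,
                                       weights=np.maximum(w0, 1e-9))))
        sd1, sd0 = max(sd1, 1e-4), max(sd0, 1e-4)
        # M-step, energy matrix: weighted logistic on soft labels
        sw = np.concatenate([np.maximum(post, 1e-9), np.maximum(1 - post, 1e-9)])
        clf.fit(Xd, yd, sample_weight=sw)
        w = -clf.coef_[0]            # p(bound) = sigmoid(a - x.w)
        a = float(clf.intercept_[0])
        # E-step on binned scores
        energy = X @ w
        prior = 1.0 / (1.0 + np.exp(-np.clip(a - energy, -500, 500)))
        pb1 = _binned_class_probs(edges, mu1, sd1)[bin_idx]
        pb0 = _binned_class_probs(edges, mu0, sd0)[bin_idx]
        num = prior * pb1
        den = num + (1.0 - prior) * pb0
        post = num / np.maximum(den, 1e-300)
        ll = float(np.sum(np.log(np.maximum(den, 1e-300))))
        fit_log.append(ll)
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            break
        ll_prev = ll

    # bound class must be the higher-score class
    if mu1 < mu0:
        post = 1.0 - post
        w, a = -w, -a
        mu1, sd1, mu0, sd0 = mu0, sd0, mu1, sd1

    # gauge: per-position minimum -> 0, intercept compensated
    mat = w.reshape(K, 4)
    shift = mat.min(axis=1)
    matrix = EnergyMatrix(mat - shift[:, None]).gauged()
    a_g = a - float(shift.sum())

    energy_g = X @ matrix.energies.ravel()
    slope, icept, *_ = stats.linregress(energy_g, scores)
    return EmaResult(
        matrix=matrix, intercept=a_g,
        posterior_bound=pd.Series(post, index=kmers, name="posterior_bound"),
        bins=edges,
        class_params={"bound": {"mu": mu1, "sd": sd1},
                      "unbound": {"mu": mu0, "sd": sd0}},
        escore_slope=float(slope), escore_intercept=float(icept),
        fit_log=fit_log,
    )


@dataclass
class KdCalibration:
    """Linear map from E-score to dissociation constant in nM.

    ``direct`` mode fits a least-squares line through >= 2 anchors (sequences
    with both an E-score and an in vitro Kd); ``slope_transfer`` borrows the
    slope of another protein's calibration and anchors the intercept on a
    single measured Kd.
    """

    slope: float        # nM per E-score unit (negative: higher score, tighter)
    intercept: float    # nM offset
    anchors: pd.DataFrame
    mode: str

    def predict(self, escore: float | np.ndarray, floor_nM: float | None = None):
        kd = self.intercept + self.slope * np.asarray(escore, dtype=float)
        if floor_nM is not None:
            kd = np.maximum(kd, floor_nM)
        return float(kd) if kd.ndim == 0 else kd

    def positive_range(self, lo: float = -0.5, hi: float = 0.5) -> tuple[float, float]:
        """E-score sub-interval of [lo, hi] with positive predicted Kd."""
        if self.slope == 0:
            return (lo, hi) if self.intercept > 0 else (np.nan, np.nan)
        x0 = -self.intercept / self.slope
        return (max(lo, x0), hi) if self.slope > 0 else (lo, min(hi, x0))


def calibrate_escore_kd(anchors: pd.DataFrame, mode: str = "direct",
                        donor_slope: float | None = None) -> KdCalibration:
    """Anchor the E-score -> Kd line on in vitro measurements."""
    need = {"escore", "kd_nM"}
    if not need.issubset(anchors.columns):
        raise ValueError(f"anchors need columns {sorted(need)}")
    x = anchors["escore"].to_numpy(dtype=float)
    y = anchors["kd_nM"].to_numpy(dtype=float)
    if mode == "direct":
        if len(anchors) < 2:
            raise ValueError("direct mode needs >= 2 anchors")
        if np.ptp(x) == 0:
            raise ValueError("zero E-score spread among anchors")
        slope, intercept, *_ = stats.linregress(x, y)
    elif mode == "slope_transfer":
        if donor_slope is None:
            raise ValueError("slope_transfer mode needs donor_slope")
        if len(anchors) < 1:
            raise ValueError("slope_transfer mode needs >= 1 anchor")
        slope = float(donor_slope)
        intercept = float(np.mean(y - slope * x))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cal = KdCalibration(float(slope), float(intercept), anchors.copy(), mode)
    pr = cal.positive_range()
    if not (pr[0] <= -0.5 + 1e-12 and pr[1] >= 0.5 - 1e-12):
        warnings.warn(f"calibration predicts non-positive Kd outside "
                      f"E-score range {pr}; clip with floor_nM when scanning")
    return cal


@dataclass
class Site:
    position: int       # 0-based window start
    strand: str
    kmer: str           # the lower-energy orientation
    energy: float
    escore: float
    kd_nM: float


@dataclass
class PromoterScan:
    sequence_id: str
    window_energies: np.ndarray    # per-position min-orientation energy (nan at ambiguity codes)
    sites: list[Site]
    total_kd_nM: float | None      # None = no predicted binding

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open intervals with strand, one row per bound site."""
        return pd.DataFrame(
            [{"chrom": self.sequence_id, "start": s.position,
              "end": s.position + K, "name": s.kmer,
              "score": s.escore, "strand": s.strand, "kd_nM": s.kd_nM}
             for s in self.sites],
            columns=["chrom", "start", "end", "name", "score", "strand", "kd_nM"])


def total_kd(site_kds: list[float]) -> float | None:
    """Aggregate per-site Kd's into a promoter total.

    Independent parallel sites contribute additive association constants, so
    1/Kd_total = sum_i 1/Kd_i; the total never exceeds the tightest single
    site, and adding a site never increases it.  Returns None for zero
    sites (explicit no-binding result).
    """
    if not site_kds:
        return None
    if any(k <= 0 for k in site_kds):
        raise ValueError("site Kd values must be positive")
    return 1.0 / sum(1.0 / k for k in site_kds)


def scan_promoter(sequence: str, ema: EmaResult, cal: KdCalibration,
                  sequence_id: str = "", posterior_threshold: float = 0.5,
                  kd_floor_nM: float = 0.01) -> PromoterScan:
    """Score every 8-bp window on both strands and call bound sites.

    Each window takes the lower energy of its two orientations; a window is
    a site when the EMA bound-posterior (logistic prior on the additive
    energy) reaches ``posterior_threshold``.  Site Kd's come from the
    energy -> E-score map passed through the anchor calibration, floored at
    ``kd_floor_nM``.  Windows containing ambiguity codes are skipped with a
    warning.
    """
    seq = str(sequence).upper()
    if len(seq) < K:
        raise ValueError(f"sequence shorter than {K} bp")
    n_win = len(seq) - K + 1
    energies = np.full(n_win, np.nan)
    sites: list[Site] = []
    n_ambig = 0
    for i in range(n_win):
        kmer = seq[i:i + K]
        if any(b not in _BASE_IDX for b in kmer):
            n_ambig += 1
            continue
        e, strand = ema.matrix.canonical_energy(kmer)
        energies[i] = e
        if ema.prior_bound(e) >= posterior_threshold:
            esc = float(ema.predict_escore(e))
            kd = float(cal.predict(esc, floor_nM=kd_floor_nM))
            sites.append(Site(i, strand, kmer if strand == "+" else revcomp(kmer),
                              e, esc, kd))
    if n_ambig:
        warnings.warn(f"skipped {n_ambig} windows containing ambiguity codes")
    return PromoterScan(sequence_id, energies, sites,
                        total_kd([s.kd_nM for s in sites]))


def variant_kd_effects(haplotypes, ema: EmaResult, cal: KdCalibration,
                       **scan_kwargs) -> pd.DataFrame:
    """Total predicted Kd per promoter haplotype (e.g. the 1001-Genomes-style
    analysis of natural variation in a clock gene promoter).

    ``haplotypes`` is an iterable of Bio.SeqRecord or (id, sequence) pairs;
    identical sequences yield identical Kd's.
    """
    rows = []
    for h in haplotypes:
        if hasattr(h, "seq"):
            hap_id, seq = h.id, str(h.seq)
        else:
            hap_id, seq = h
        scan = scan_promoter(seq, ema, cal, sequence_id=hap_id, **scan_kwargs)
        rows.append({"haplotype": hap_id, "n_sites": len(scan.sites),
                     "total_kd_nM": scan.total_kd_nM})
    if not rows:
        raise ValueError("empty haplotype set")
    return pd.DataFrame(rows)


def inject_reporter_gene(model: ClockModel, kd_nM: float, target: str,
                         qc: QuantConstants = QuantConstants(),
                         regulator: str | None = None,
                         name: str | None = None) -> ClockModel:
    """Add a transcription-only reporter copy of a clock gene with a
    sequence-derived Kd.

    The reporter duplicates the target mRNA's transcription/degradation
    equation, with the regulator's dissociation-constant parameter replaced
    by ``kd_nM`` (converted to copies/cell) and no protein production.  It is
    integrated after the core model, so core trajectories are unchanged.
    """
    if kd_nM <= 0:
        raise ValueError("kd_nM must be positive")
    entries = [r for r in model.kd_map if r["target"] == target]
    if regulator is not None:
        entries = [r for r in entries if r["regulator"] == regulator]
    if not entries:
        raise KeyError(f"no Kd-mapped regulator for target {target!r}")
    if len(entries) > 1 and regulator is None:
        regs = [r["regulator"] for r in entries]
        raise ValueError(f"target {target!r} has several regulators {regs}; "
                         "pass regulator=")
    entry = entries[0]
    param = entry["parameter"]
    name = name or f"{target}_rep"
    new_param = f"{param}_{name}"

    factor = model.scaled_parameters.get(param)
    fval = model.parameters[factor] if factor else 1.0
    value = float(conc_to_copies(kd_nM, qc)) / fval

    import re as _re
    expr = model.rates[target]
    expr = _re.sub(rf"\b{_re.escape(param)}\b", new_param, expr)
    expr = _re.sub(rf"\b{_re.escape(target)}\b", name, expr)

    out = model.copy()
    out.parameters[new_param] = value
    if factor:
        out.scaled_parameters[new_param] = factor
    out = add_driven_species(out, name, expr, init=target)
    return out
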