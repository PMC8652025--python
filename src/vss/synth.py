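"""Synthetic replicate tracks with a known mean–variance relationship.

The generator emulates a zero-inflated, coverage-style genomic signal: each
fixed-width bin carries a latent mean ``mu_i`` — a small background level
for most positions, a heavy-tailed (log-normal) signal level for the rest —
and each replicate observes an independent draw from a noise model
conditioned on ``mu_i``:

* ``poisson`` — ``sigma_true(mu) = sqrt(mu)``;
* ``negative_binomial`` with dispersion ``phi`` —
  ``sigma_true(mu) = sqrt(mu + phi*mu**2)`` (the default: its
  super-Poisson, non-linear sd is the regime where neither log nor asinh
  stabilizes variance);
* ``gaussian`` — real-valued signals with the same sd law (or a custom
  ``sigma_fn``), emulating non-count tracks.

Background positions receive a small *non-zero* mean (stray reads) rather
than an exact zero: this reproduces the key feature of real zero-inflated
tracks that positions reading 0 in one replicate still show noise in the
other — precisely the situation the zero bin of the estimator addresses.
Setting ``background_mean=0`` yields structurally silent background.

Replicates are i.i.d. given ``mu_i`` (no batch effects), and a fixed seed
reproduces output bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .errors import ValidationError
from .mv_curve import BaseAuxPairs
from .signal_io import ReplicateSet, SignalTrack, write_bedgraph

NOISE_MODELS = ("poisson", "negative_binomial", "gaussian")


@dataclass
class SimConfig:
    """Study conditions for the replicate-track simulator.

    Defaults mirror a desk-scale two-chromosome ChIP-seq-like setting:
    100 kb of 25 bp bins per chromosome, 60% background positions at a mean
    of 0.5 reads, log-normal signal means centred on 20 reads, and two
    negative-binomial replicates with dispersion 0.1.
    """

    n_positions: int = 100_000          # bins per chromosome
    chromosomes: tuple = ("chr21", "chr22")
    bin_width: int = 25                 # bp per bin
    zero_fraction: float = 0.6          # fraction of background positions
    background_mean: float = 0.5        # latent mean at background positions
    mu_log_mean: float = float(np.log(20.0))   # log-normal location of signal means
    mu_log_sd: float = 0.8                     # log-normal scale of signal means
    peak_fraction: float = 0.0          # optional extra high-signal component
    peak_mu_scale: float = 10.0         # multiplier on signal means inside peaks
    noise_model: str = "negative_binomial"
    phi: float = 0.1                    # NB dispersion: var = mu + phi*mu**2
    m_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.zero_fraction <= 1.0):
            raise ValidationError("zero_fraction must be in [0, 1]")
        if self.background_mean < 0:
            raise ValidationError("background_mean must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"noise_model must be one of {NOISE_MODELS}")
        if self.phi < 0:
            raise ValidationError("dispersion phi must be non-negative")
        if self.m_replicates < 2:
            raise ValidationError("m_replicates must be at least 2")
        if not (0.0 <= self.peak_fraction < 1.0):
            raise ValidationError("peak_fraction must be in [0, 1)")
        if self.n_positions < 1:
            raise ValidationError("n_positions must be positive")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulation: per-position latent means
    (aligned with the emitted track intervals) and the analytic
    ``sigma_true(mu)`` implied by the noise model."""

    mu: np.ndarray
    sigma_true: Callable[[np.ndarray], np.ndarray]
    config: SimConfig = field(repr=False, default=None)


def _sigma_true_fn(config: SimConfig, sigma_fn=None) -> Callable:
    if sigma_fn is not None:
        return sigma_fn
    if config.noise_model == "poisson":
        return lambda mu: np.sqrt(np.asarray(mu, dtype=np.float64))
    # negative_binomial and the default gaussian law share var = mu + phi*mu^2
    phi = config.phi
    return lambda mu: np.sqrt(np.asarray(mu, dtype=np.float64) * (1.0 + phi * np.asarray(mu, dtype=np.float64)))


def simulate_replicates(
    config: SimConfig,
    sigma_fn: Optional[Callable] = None,
) -> tuple[ReplicateSet, SimTruth]:
    """Draw latent means and replicate tracks under ``config``.

    ``sigma_fn`` optionally overrides the Gaussian noise sd law (ignored for
    count models).  Returns an aligned :class:`ReplicateSet` (signal type
    ``raw`` for count models, ``lppv`` for Gaussian, whose values may be
    negative) and the matching :class:`SimTruth`.
    """
    rng = np.random.default_rng(config.seed)
    sig_true = _sigma_true_fn(config, sigma_fn)

    chrom_mu = {}
    chrom_reps = {}
    for chrom in config.chromosomes:
        n = config.n_positions
        is_background = rng.random(n) < config.zero_fraction
        mu = rng.lognormal(config.mu_log_mean, config.mu_log_sd, n)
        if config.peak_fraction > 0:
            mu = np.where(rng.random(n) < config.peak_fraction, mu * config.peak_mu_scale, mu)
        mu = np.where(is_background, config.background_mean, mu)
        reps = np.empty((config.m_replicates, n))
        for r in range(config.m_replicates):
            reps[r] = _draw(rng, mu, config, sig_true)
        chrom_mu[chrom] = mu
        chrom_reps[chrom] = reps

    # assemble tracks (chromosomes in sorted order, matching SignalTrack)
    chroms_sorted = sorted(config.chromosomes)
    chrom_col = np.concatenate(
        [np.full(config.n_positions, c, dtype=object) for c in chroms_sorted]
    )
    starts = np.concatenate(
        [np.arange(config.n_positions, dtype=np.int64) * config.bin_width for _ in chroms_sorted]
    )
    ends = starts + config.bin_width
    tracks = []
    for r in range(config.m_replicates):
        values = np.concatenate([chrom_reps[c][r] for c in chroms_sorted])
        tracks.append(SignalTrack(chrom_col, starts, ends, values))
    signal_type = "lppv" if config.noise_model == "gaussian" else "raw"
    reps_set = ReplicateSet(tracks, signal_type)
    truth = SimTruth(
        mu=np.concatenate([chrom_mu[c] for c in chroms_sorted]),
        sigma_true=sig_true,
        config=config,
    )
    return reps_set, truth


def _draw(rng, mu, config: SimConfig, sig_true) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(mu).astype(np.float64)
    if config.noise_model == "negative_binomial":
        if config.phi == 0:
            return rng.poisson(mu).astype(np.float64)
        out = np.zeros_like(mu)
        pos = mu > 0
        p = 1.0 / (1.0 + config.phi * mu[pos])
        out[pos] = rng.negative_binomial(1.0 / config.phi, p).astype(np.float64)
        return out
    return mu + sig_true(mu) * rng.standard_normal(len(mu))


def simulate_calibration_pairs(
    n: int,
    sigma_fn: Callable,
    seed: int = 0,
    mu_log_mean: float = float(np.log(20.0)),
    mu_log_sd: float = 0.8,
) -> BaseAuxPairs:
    """Gaussian pairs whose conditional law is exactly
    ``aux | base ~ N(base, sigma_fn(base))``.

    Base values are latent means drawn from the log-normal mean law; the
    auxiliary value adds Gaussian noise with the known sd.  This is the
    regime in which the Gaussian quality-of-fit score is provably maximized
    by the true curve, so it serves to calibrate likelihood comparisons.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mu_log_mean, mu_log_sd, n)
    aux = base + np.asarray(sigma_fn(base)) * rng.standard_normal(n)
    return BaseAuxPairs(base, aux)


def write_simulation(outdir, reps: ReplicateSet, truth: SimTruth) -> dict:
    """Write ``rep<k>.bedgraph`` files, ``truth.tsv`` (chrom, start, end,
    mu_true) and ``config.json`` into ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for k, track in enumerate(reps.tracks, start=1):
        p = outdir / f"rep{k}.bedgraph"
        write_bedgraph(track, p)
        paths[f"rep{k}"] = str(p)
    grid = reps.tracks[0]
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tstart\tend\tmu_true\n")
        for chrom, start, end, mu in zip(grid.chroms, grid.starts, grid.ends, truth.mu):
            fh.write(f"{chrom}\t{start}\t{end}\t{mu:.10g}\n")
    paths["truth"] = str(truth_path)
    config_path = outdir / "config.json"
    with open(config_path, "w") as fh:
        cfg = asdict(truth.config)
        cfg["chromosomes"] = list(cfg["chromosomes"])
        json.dump(cfg, fh, indent=2)
        fh.write("\n")
    paths["config"] = str(config_path)
    return paths
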