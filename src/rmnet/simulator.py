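"""Benchmark simulator: a 10-OTU gut community driven by 3 latent factors.

The community is generated by a cascade of tanh response equations: two
source OTUs respond to a latent factor, and the remaining eight respond to
upstream OTUs (and occasionally a latent factor), so the inter-OTU
coefficient signs define a known ground-truth signed network of 14 directed
edges.  Latent factors are i.i.d. Uniform(0, 1) per time point; per-OTU
Gaussian noise is scaled by the noiseless series variance divided by an
integer signal-to-noise ratio drawn uniformly from 4..12, with medium and
high regimes at 5x and 10x the low-noise scale.  All abundances are clipped
to [0, 1] as they are produced, so noisy values feeding downstream equations
remain valid proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .triplet_scan import COMPETITIVE, COOPERATIVE, RegulatoryNetwork

__all__ = [
    "NOISE_LEVELS",
    "SimulationConfig",
    "SimulatedDataset",
    "ground_truth_network",
    "ground_truth_adjacency",
    "evaluate_equations",
    "noise_sigma",
    "sample_snr",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

N_OTUS = 10
N_LATENT = 3
NOISE_LEVELS = ("none", "low", "medium", "high")
_NOISE_MULT = {"none": 0.0, "low": 1.0, "medium": 5.0, "high": 10.0}

# (source OTU, target OTU, sign) from the inter-OTU coefficient signs of the
# generating equations; latent-factor edges are excluded (unobserved).
GROUND_TRUTH_EDGES = (
    (1, 3, COMPETITIVE),
    (1, 4, COOPERATIVE),
    (2, 4, COMPETITIVE),
    (3, 4, COMPETITIVE),
    (2, 5, COOPERATIVE),
    (3, 5, COMPETITIVE),
    (5, 6, COOPERATIVE),
    (3, 6, COMPETITIVE),
    (5, 7, COMPETITIVE),
    (6, 9, COMPETITIVE),
    (7, 9, COOPERATIVE),
    (8, 9, COOPERATIVE),
    (7, 10, COMPETITIVE),
    (8, 10, COOPERATIVE),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults are the benchmark conditions: 13 time points, SNR integers in
    4..12, one of four noise regimes.
    """

    n_timepoints: int = 13
    noise_level: str = "none"
    snr_min: int = 4
    snr_max: int = 12
    seed: int | None = None

    def __post_init__(self):
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if self.noise_level not in NOISE_LEVELS:
            raise ValueError(f"noise_level must be one of {NOISE_LEVELS}")
        if not (1 <= self.snr_min <= self.snr_max):
            raise ValueError("SNR range must be positive integers, min <= max")


@dataclass
class SimulatedDataset:
    """A generated abundance matrix plus everything needed to evaluate it."""

    abundances: np.ndarray  # (10, T), clipped to [0, 1]
    latent: np.ndarray  # (3, T)
    noise: np.ndarray  # (10, T)
    snr: np.ndarray  # (10,) integers
    truth: RegulatoryNetwork
    config: SimulationConfig
    otu_ids: list = field(default_factory=lambda: [f"O{i}" for i in range(1, 11)])


def ground_truth_network() -> RegulatoryNetwork:
    """The 14-edge signed directed network wired into the generating equations."""
    net = RegulatoryNetwork()
    for src, tgt, sign in GROUND_TRUTH_EDGES:
        net.add_edge(f"O{src}", f"O{tgt}", sign)
    return net


def ground_truth_adjacency():
    """Truth as boolean (10, 10) matrices ``(cooperative, competitive)``, 0-based."""
    coop = np.zeros((N_OTUS, N_OTUS), dtype=bool)
    comp = np.zeros((N_OTUS, N_OTUS), dtype=bool)
    for src, tgt, sign in GROUND_TRUTH_EDGES:
        (coop if sign == COOPERATIVE else comp)[src - 1, tgt - 1] = True
    return coop, comp


def evaluate_equations(latent: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Evaluate the ten response equations for given latent and noise draws.

    Rows are computed in order O1..O10 so downstream OTUs see the (noisy,
    clipped) upstream abundances.  Each row is clipped to [0, 1] immediately;
    the number of clipped entries is logged at debug level.
    """
    F = np.atleast_2d(np.asarray(latent, dtype=float))
    N = np.atleast_2d(np.asarray(noise, dtype=float))
    if F.shape[0] != N_LATENT or N.shape[0] != N_OTUS or F.shape[1] != N.shape[1]:
        raise ValueError("latent must be (3, T) and noise (10, T)")
    T = F.shape[1]
    O = np.empty((N_OTUS, T))
    F1, F2, F3 = F

    def row(i, values):
        clipped = np.clip(values, 0.0, 1.0)
        n_out = int(np.count_nonzero(values != clipped))
        if n_out:
            logger.debug("O%d: %d of %d values clipped to [0, 1]", i, n_out, T)
        O[i - 1] = clipped

    row(1, 1.3 * np.tanh(-0.1 * F2 + 0.25) + N[0])
    row(2, 1.1 * np.tanh(0.35 * F2 + 0.1) + N[1])
    row(3, np.tanh(-0.56 * O[0] + 0.4 * F1 + 0.5) + N[2])
    row(4, np.tanh(0.6 * O[0] - 0.15 * O[1] - 0.1 * O[2] + 0.1) + N[3])
    row(5, np.tanh(0.24 * O[1] - 0.75 * O[2] - 0.05 * F1 + 0.3) + N[4])
    row(6, 1.4 * np.tanh(0.2 * O[4] - 0.2 * O[2] + 0.15) + N[5])
    row(7, 1.3 * np.tanh(-0.15 * O[4] + 0.2) + N[6])
    row(8, np.tanh(-0.15 * F3 + 0.2) + N[7])
    row(9, np.tanh(-0.41 * O[5] + 0.55 * O[6] + 0.35 * O[7] + 0.18) + N[8])
    row(10, np.tanh(-0.45 * O[6] + 0.7 * O[7] + 0.1 * F3 + 0.25) + N[9])
    return O


def noise_sigma(otu_variance, snr, level: str):
    """Gaussian noise scale for one OTU.

    ``low = variance / snr``; ``medium = 5 * low``; ``high = 10 * low``;
    ``none = 0``.  The variance is that of the OTU's noiseless series.
    """
    if level not in NOISE_LEVELS:
        raise ValueError(f"level must be one of {NOISE_LEVELS}")
    var = np.asarray(otu_variance, dtype=float)
    snr = np.asarray(snr)
    if np.any(var < 0) or np.any(snr < 1):
        raise ValueError("variance must be >= 0 and snr >= 1")
    return _NOISE_MULT[level] * var / snr


def sample_snr(rng: np.random.Generator, n_otus: int = N_OTUS, snr_min: int = 4, snr_max: int = 12):
    """Per-OTU integer signal-to-noise ratios, uniform on {snr_min..snr_max}."""
    return rng.integers(snr_min, snr_max + 1, size=n_otus)


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Generate one benchmark dataset under ``cfg``; reproducible from its seed.

    The latent matrix is drawn first, the noiseless cascade fixes each OTU's
    series variance, and the noise matrix is then drawn with per-OTU scale
    from :func:`noise_sigma` and added inside a second cascade evaluation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    T = cfg.n_timepoints
    F = rng.uniform(0.0, 1.0, size=(N_LATENT, T))
    snr = sample_snr(rng, snr_min=cfg.snr_min, snr_max=cfg.snr_max)
    if cfg.noise_level == "none":
        N = np.zeros((N_OTUS, T))
    else:
        clean = evaluate_equations(F, np.zeros((N_OTUS, T)))
        sigma = noise_sigma(clean.var(axis=1, ddof=1), snr, cfg.noise_level)
        N = rng.normal(0.0, 1.0, size=(N_OTUS, T)) * sigma[:, None]
    O = evaluate_equations(F, N)
    return SimulatedDataset(
        abundances=O,
        latent=F,
        noise=N,
        snr=snr,
        truth=ground_truth_network(),
        config=cfg,
    )
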