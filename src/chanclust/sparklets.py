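"""Quantal Ca²⁺ sparklet analysis: idealization, nPs, and coupled gating.

A sparklet site is a small group of L-type Ca²⁺ channels whose openings
produce quantized elevations of near-membrane fluorescence.  This module
idealizes a trace into an integer open-channel level per frame, summarizes
site activity as nPs (the time-weighted mean number of open channels), and
estimates the coupling coefficient κ of the channels at the site under a
coupled binary Markov chain:

    P = (1 - κ) · P_indep + κ · P_sync

where ``P_indep`` lets each of the N channels gate as an independent
two-state (closed/open) chain with stationary open probability p, and
``P_sync`` moves all channels to a common fate drawn from the same
single-channel law.  κ = 0 therefore means fully independent gating and
κ = 1 means all channels open and close simultaneously.

The aggregate open-channel count is itself a Markov chain on {0, ..., N}
(channels are exchangeable), which is what both the simulator and the
maximum-likelihood estimator operate on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import SparkletTrace

#: Activity cutoff separating low- from high-activity sparklet sites.
NPS_CUTOFF = 0.2

#: Default mean open time of a single channel, in frames (at 100 Hz).
DEFAULT_MEAN_OPEN_FRAMES = 2.0


# ---------------------------------------------------------------------------
# Coupled-chain kernel


def single_channel_rates(open_prob: float, mean_open_frames: float = DEFAULT_MEAN_OPEN_FRAMES):
    """Per-frame opening/closing probabilities of one two-state channel.

    The closing probability is ``beta = 1 / mean_open_frames`` and the
    opening probability ``alpha`` follows from stationarity
    ``p * beta = (1 - p) * alpha``.
    """
    if not 0 < open_prob < 1:
        raise ValueError("open_prob must lie strictly between 0 and 1")
    if mean_open_frames < 1:
        raise ValueError("mean open time must be at least one frame")
    beta = 1.0 / mean_open_frames
    alpha = open_prob * beta / (1.0 - open_prob)
    if alpha >= 1.0:
        raise ValueError(
            f"open_prob={open_prob} too large for mean_open_frames={mean_open_frames}; "
            "per-frame opening probability would exceed 1"
        )
    return alpha, beta


def coupled_transition_matrix(
    n_channels: int,
    open_prob: float,
    kappa: float,
    mean_open_frames: float = DEFAULT_MEAN_OPEN_FRAMES,
) -> np.ndarray:
    """Transition matrix of the aggregate open count k ∈ {0..N}.

    Independent component: from level k, ``Binom(k, 1-beta)`` channels stay
    open and ``Binom(N-k, alpha)`` closed channels open.  Synchronized
    component: a single representative channel (open with probability k/N)
    makes one two-state transition and every channel adopts its outcome,
    so mass goes only to levels 0 and N.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not 0 <= kappa <= 1:
        raise ValueError("kappa must lie in [0, 1]")
    alpha, beta = single_channel_rates(open_prob, mean_open_frames)
    N = n_channels
    ks = np.arange(N + 1)

    # independent kernel: convolution of the two binomials
    p_ind = np.zeros((N + 1, N + 1))
    for k in ks:
        stay = stats.binom.pmf(np.arange(k + 1), k, 1.0 - beta)
        new = stats.binom.pmf(np.arange(N - k + 1), N - k, alpha)
        p_ind[k, : N + 1] = np.convolve(stay, new)[: N + 1]

    # synchronized kernel
    p_sync = np.zeros((N + 1, N + 1))
    frac_open = ks / N
    to_all_open = frac_open * (1.0 - beta) + (1.0 - frac_open) * alpha
    p_sync[:, N] = to_all_open
    p_sync[:, 0] += 1.0 - to_all_open

    return (1.0 - kappa) * p_ind + kappa * p_sync


def coupled_initial_distribution(n_channels: int, open_prob: float, kappa: float) -> np.ndarray:
    """Stationary-style initial law: binomial with prob 1-κ, all-or-none with prob κ."""
    N = n_channels
    binom = stats.binom.pmf(np.arange(N + 1), N, open_prob)
    sync = np.zeros(N + 1)
    sync[0] = 1.0 - open_prob
    sync[N] += open_prob
    return (1.0 - kappa) * binom + kappa * sync


# ---------------------------------------------------------------------------
# Idealization and nPs


@dataclass
class QuantalConfig:
    """Calibration for quantal idealization.

    ``quantal_amplitude`` is the fluorescence increment per open channel;
    frames are assigned to the nearest integer multiple (half-amplitude
    thresholds).  ``max_levels`` caps the level at the number of quantal
    levels the detector may assign.
    """

    quantal_amplitude: float
    max_levels: int = 10

    def __post_init__(self) -> None:
        if self.quantal_amplitude <= 0:
            raise ValueError("quantal_amplitude must be positive")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")


@dataclass
class IdealizedRecord:
    """Integer open-channel level per frame for one sparklet site."""

    levels: np.ndarray
    n_levels_reached: int
    duration_frames: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if np.any(self.levels < 0):
            raise ValueError("levels must be non-negative")

    @classmethod
    def from_levels(cls, levels: np.ndarray) -> "IdealizedRecord":
        levels = np.asarray(levels, dtype=int)
        n_reached = int(levels.max()) if levels.size else 0
        return cls(levels=levels, n_levels_reached=n_reached, duration_frames=len(levels))


@dataclass
class SiteActivity:
    """nPs of one site and its low/high classification (cutoff 0.2)."""

    nPs: float
    activity_class: str
    cutoff: float = NPS_CUTOFF


@dataclass
class CouplingEstimate:
    """Maximum-likelihood coupling coefficient for one sparklet site.

    ``kappa`` is NaN (and ``identifiable`` False) for N = 1, where the
    independent and synchronized kernels coincide.
    """

    kappa: float
    open_prob: float
    log_likelihood: float
    n_channels: int
    identifiable: bool = True


def detect_and_idealize(trace: SparkletTrace, config: QuantalConfig) -> IdealizedRecord:
    """Assign each frame to its nearest quantal level.

    Half-amplitude thresholds: a frame at signal s maps to
    ``round(s / quantal_amplitude)``, clipped to ``[0, max_levels]``.
    """
    q = config.quantal_amplitude
    levels = np.rint(trace.samples / q).astype(int)
    levels = np.clip(levels, 0, config.max_levels)
    return IdealizedRecord.from_levels(levels)


def compute_nPs(record: IdealizedRecord, cutoff: float = NPS_CUTOFF) -> SiteActivity:
    """Site activity nPs = Σ_k k·T_k / T (time-weighted mean open count).

    Sites with nPs strictly above the cutoff are classed ``high``.
    """
    if record.duration_frames <= 0:
        raise ValueError("record must contain at least one frame")
    nps = float(record.levels.mean())
    cls = "high" if nps > cutoff else "low"
    return SiteActivity(nPs=nps, activity_class=cls, cutoff=cutoff)


# ---------------------------------------------------------------------------
# κ estimation


def _negative_log_likelihood(
    params: np.ndarray,
    counts: np.ndarray,
    first_level: int,
    n_channels: int,
    mean_open_frames: float,
) -> float:
    kappa, p = params
    kappa = min(max(kappa, 0.0), 1.0)
    p = min(max(p, 1e-6), 1.0 / (1.0 + 1.0 / mean_open_frames) - 1e-6)
    try:
        P = coupled_transition_matrix(n_channels, p, kappa, mean_open_frames)
    except ValueError:
        return 1e12
    pi0 = coupled_initial_distribution(n_channels, p, kappa)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        logP = np.log(P)
    if np.any(~np.isfinite(logP[mask])):
        return 1e12
    ll = float(np.sum(counts[mask] * logP[mask]))
    if pi0[first_level] <= 0:
        return 1e12
    ll += math.log(pi0[first_level])
    return -ll


def estimate_kappa(
    record: IdealizedRecord,
    n_channels: int,
    mean_open_frames: float = DEFAULT_MEAN_OPEN_FRAMES,
) -> CouplingEstimate:
    """Fit (κ, p) by maximum likelihood on the aggregate level sequence.

    The likelihood of the observed level path is a product over frame
    transitions of the aggregate coupled-chain kernel; it is maximized by
    a coarse grid search over (κ, p) followed by bounded local refinement.
    Records shorter than 100 frames are rejected as uninformative, and for
    a single channel κ is flagged as unidentifiable.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if record.duration_frames < 100:
        raise ValueError("record must be at least 100 frames long")
    if record.n_levels_reached > n_channels:
        raise ValueError(
            f"record reaches level {record.n_levels_reached} but only "
            f"{n_channels} channels were specified"
        )

    levels = record.levels
    N = n_channels
    # transition count matrix
    counts = np.zeros((N + 1, N + 1))
    np.add.at(counts, (levels[:-1], levels[1:]), 1.0)
    first = int(levels[0])

    if n_channels == 1:
        # mixture components coincide: estimate p only, flag κ undefined
        p_hat = float(np.clip(levels.mean(), 1e-3, 0.6))
        nll = _negative_log_likelihood(np.array([0.0, p_hat]), counts, first, 1, mean_open_frames)
        return CouplingEstimate(
            kappa=float("nan"),
            open_prob=p_hat,
            log_likelihood=-nll,
            n_channels=1,
            identifiable=False,
        )

    p_max = 1.0 / (1.0 + 1.0 / mean_open_frames) - 1e-4
    kappa_grid = np.linspace(0.0, 1.0, 11)
    p_grid = np.linspace(0.01, min(0.6, p_max), 9)
    best = None
    for kap in kappa_grid:
        for p in p_grid:
            nll = _negative_log_likelihood(
                np.array([kap, p]), counts, first, N, mean_open_frames
            )
            if best is None or nll < best[0]:
                best = (nll, kap, p)

    res = optimize.minimize(
        _negative_log_likelihood,
        x0=np.array([best[1], best[2]]),
        args=(counts, first, N, mean_open_frames),
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (1e-4, p_max)],
    )
    if res.fun <= best[0]:
        kap_hat, p_hat, nll = float(res.x[0]), float(res.x[1]), float(res.fun)
    else:  # fall back to the grid optimum if the polish step diverged
        nll, kap_hat, p_hat = best
    return CouplingEstimate(
        kappa=float(np.clip(kap_hat, 0.0, 1.0)),
        open_prob=p_hat,
        log_likelihood=-nll,
        n_channels=N,
    )


# ---------------------------------------------------------------------------
# Per-cell summaries


def site_summary(activities: list[SiteActivity]) -> dict:
    """Summarize the sparklet sites of one cell.

    Cells with no detected sites contribute nPs = 0 to the all-site mean,
    so silent cells count as zero activity rather than being dropped.
    """
    n_sites = len(activities)
    low = [a.nPs for a in activities if a.activity_class == "low"]
    high = [a.nPs for a in activities if a.activity_class == "high"]
    all_mean = float(np.mean([a.nPs for a in activities])) if activities else 0.0
    return {
        "sites_per_cell": n_sites,
        "mean_nPs_low": float(np.mean(low)) if low else float("nan"),
        "mean_nPs_high": float(np.mean(high)) if high else float("nan"),
        "mean_nPs_all": all_mean,
    }
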