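"""Synthetic single-cell fluorescence data and subpopulation estimation.

The experimental readout of transfer-competence activation is a per-cell
fluorescence distribution: a large non-activated background population and a
minority activated subpopulation whose median intensity is set by the
feedback loop and therefore does not move with the input level.  Both
components are modelled as log-normal (reporter distributions are strongly
right-skewed, which is also why the skew-robust 75th-percentile summary is
used for group comparisons).

The activated fraction is estimated by quantile-quantile comparison against
a reference background distribution: fit the background on the lower ranks
of the ordered sample, and find the quantile above which the empirical
values persistently exceed the fitted quantiles plus a deviation envelope.
The estimated activated fraction is one minus that breakpoint quantile.
This is a documented reconstruction of the qq-plot subpopulation method;
its deviation multiplier ``k`` and background-fit window are repository
calibrations (see analysis/00_calibrate.py), not published constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import EnsembleResult

__all__ = [
    "FluorescenceSample",
    "SubpopEstimate",
    "generate_cells",
    "link_ensemble",
    "qq_subpopulation_estimate",
    "percentile_summary",
    "DEFAULT_BACKGROUND",
    "DEFAULT_ACTIVE",
]

#: Log-normal component defaults in arbitrary units (AU) at fixed exposure.
#: The activated median sits 10x above background, the separation regime of
#: a well-induced reporter.
DEFAULT_BACKGROUND = {"median": 100.0, "sigma": 0.25}
DEFAULT_ACTIVE = {"median": 1000.0, "sigma": 0.35}


@dataclass
class FluorescenceSample:
    """Per-cell intensities (AU, > 0) with ground-truth labels when synthetic."""

    intensities: np.ndarray
    labels: np.ndarray | None = None      # True = activated; None for external data
    true_active_fraction: float | None = None
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.intensities)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell": np.arange(self.n), "intensity_au": self.intensities})
        if self.labels is not None:
            df["active"] = self.labels.astype(int)
        return df


@dataclass
class SubpopEstimate:
    """Result of the qq-based activated-fraction estimate."""

    estimated_fraction: float
    breakpoint_quantile: float
    mu: float                 # fitted background location (log scale for lognormal)
    sigma: float              # fitted background spread
    reference: str
    k: float
    n: int
    n_exceeding: int
    residual_rms: float       # background-fit residual RMS over the fit window

    def to_dict(self) -> dict:
        return {
            "estimated_fraction": self.estimated_fraction,
            "breakpoint_quantile": self.breakpoint_quantile,
            "mu": self.mu,
            "sigma": self.sigma,
            "reference": self.reference,
            "k": self.k,
            "n": self.n,
            "n_exceeding": self.n_exceeding,
            "residual_rms": self.residual_rms,
        }


def _check_component(name, params):
    if params.get("median", 0) <= 0 or params.get("sigma", 0) <= 0:
        raise ValueError(f"{name} params need positive 'median' and 'sigma', got {params}")


def generate_cells(
    n: int,
    active_fraction: float,
    background_params: dict | None = None,
    active_params: dict | None = None,
    rng: np.random.Generator | int | None = None,
) -> FluorescenceSample:
    """Draw a two-component log-normal intensity mixture with known labels.

    Each cell is activated with probability ``active_fraction``; intensities
    are log-normal with the component's median and log-scale sigma.  The
    activated median must exceed the background median.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= active_fraction <= 1:
        raise ValueError("active_fraction must be in [0, 1]")
    bg = dict(DEFAULT_BACKGROUND, **(background_params or {}))
    ac = dict(DEFAULT_ACTIVE, **(active_params or {}))
    _check_component("background", bg)
    _check_component("active", ac)
    if ac["median"] <= bg["median"]:
        raise ValueError("activated median must exceed background median")
    rng = np.random.default_rng(rng)
    labels = rng.random(n) < active_fraction
    z = rng.standard_normal(n)
    mu = np.where(labels, np.log(ac["median"]), np.log(bg["median"]))
    sig = np.where(labels, ac["sigma"], bg["sigma"])
    return FluorescenceSample(
        intensities=np.exp(mu + sig * z),
        labels=labels,
        true_active_fraction=float(active_fraction),
        params={"background": bg, "active": ac, "n": n},
    )


def link_ensemble(
    ensemble: EnsembleResult,
    species: str,
    gain: float = 10.0,
    background_params: dict | None = None,
    rng: np.random.Generator | int | None = None,
) -> FluorescenceSample:
    """Model-to-measurement bridge: intensity = background draw + gain * count.

    Zero-state cells therefore sample the pure background (autofluorescence)
    distribution; positive-state cells are shifted up proportionally to
    their endpoint regulator count.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    bg = dict(DEFAULT_BACKGROUND, **(background_params or {}))
    _check_component("background", bg)
    rng = np.random.default_rng(rng)
    counts = ensemble.endpoint(species)
    backgrounds = np.exp(np.log(bg["median"]) + bg["sigma"] * rng.standard_normal(len(counts)))
    labels = counts > 0
    return FluorescenceSample(
        intensities=backgrounds + gain * counts,
        labels=labels,
        true_active_fraction=float(labels.mean()),
        params={"background": bg, "gain": gain, "species": species},
    )


def qq_subpopulation_estimate(
    sample,
    reference: str = "lognormal",
    fit_window: float = 0.5,
    k: float = 2.0,
    persistence: float = 0.95,
    min_n: int = 100,
) -> SubpopEstimate:
    """Estimate the activated-cell fraction from an intensity distribution.

    Procedure: order the intensities; fit the reference family (log-normal by
    default, optionally normal) to the lower ``fit_window`` fraction of ranks
    by regressing the (log-)values on standard-normal plotting-position
    quantiles; form a deviation envelope ``fitted quantile + k * fitted
    sigma``; the breakpoint is the lowest rank above which at least
    ``persistence`` of all higher-ranked cells exceed the envelope; the
    estimated fraction counts the envelope-exceeding cells above the
    breakpoint (counting the whole tail would systematically overshoot by
    the tolerated non-exceeding share).

    Below ~100 cells the rank quantiles are too coarse for a stable
    breakpoint, so smaller samples are rejected.  The background fit assumes
    the activated cells are confined to ranks above ``fit_window``: once the
    activated fraction exceeds ``1 - fit_window`` the fitted "background"
    absorbs part of the activated mode and the estimate degrades.
    """
    values = sample.intensities if isinstance(sample, FluorescenceSample) else np.asarray(sample, dtype=float)
    n = len(values)
    if n < min_n:
        raise ValueError(f"need at least {min_n} cells, got {n}")
    if (values <= 0).any():
        raise ValueError("intensities must be positive")
    if reference not in ("lognormal", "normal"):
        raise ValueError("reference must be 'lognormal' or 'normal'")
    if not 0 < fit_window <= 1:
        raise ValueError("fit_window must be in (0, 1]")

    x = np.sort(values)
    y = np.log(x) if reference == "lognormal" else x
    p = (np.arange(1, n + 1) - 0.5) / n
    z = stats.norm.ppf(p)

    m = max(int(np.floor(fit_window * n)), 10)
    zf, yf = z[:m], y[:m]
    sigma, mu = np.polyfit(zf, yf, 1)
    if sigma <= 0:
        sigma = max(float(np.std(yf)), 1e-12)
    resid = yf - (mu + sigma * zf)
    envelope = mu + sigma * z + k * sigma
    exceed = y > envelope

    # suffix scan: lowest rank j with >= persistence of ranks >= j exceeding
    suffix = np.cumsum(exceed[::-1])[::-1]  # suffix[j] = # exceeding among ranks j..n-1
    tail_n = n - np.arange(n)
    ok = suffix >= persistence * tail_n
    idx = np.nonzero(ok)[0]
    if idx.size == 0 or suffix[idx[0]] == 0:
        frac = 0.0
        breakpoint_q = 1.0
        n_exc = int(exceed.sum())
    else:
        j = int(idx[0])
        breakpoint_q = j / n
        n_exc = int(suffix[j])
        frac = n_exc / n
    return SubpopEstimate(
        estimated_fraction=float(frac),
        breakpoint_quantile=float(breakpoint_q),
        mu=float(mu),
        sigma=float(sigma),
        reference=reference,
        k=float(k),
        n=n,
        n_exceeding=n_exc,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def percentile_summary(sample, q: float) -> float:
    """Empirical q-quantile with linear interpolation between order statistics.

    q = 0.75 is the conventional skew-robust summary for reporter
    distributions; the convention matches numpy's default ("linear",
    Hyndman-Fan type 7), so [1, 2, 3, 4] at q = 0.5 gives 2.5.
    """
    values = sample.intensities if isinstance(sample, FluorescenceSample) else np.asarray(sample, dtype=float)
    if len(values) == 0:
        raise ValueError("empty sample")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(values, q))
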