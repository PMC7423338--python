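"""Regulatory-network data model for the ICEclc transfer-competence switch.

The switch is modelled as a small cascade of transcription-factor nodes:
an upstream activator (TciR) drives production of an intermediary regulator
(BisR), which transiently "kickstarts" the *alpA* promoter; the product of
that promoter (BisDC) activates the same promoter again, closing an
autoregulatory positive-feedback loop, and additionally drives downstream
("late") transfer-competence genes.

Each node is an abstract operator: a promoter that is either free or bound
by exactly one activator oligomer, with mass-action binding of ``n`` free
monomers, first-order unbinding, zero-order production while bound, and
first-order degradation of free monomers.  A :class:`NetworkModel` is a
declarative description of species and promoters; :func:`compile_network`
lowers it to flat arrays of reaction channels consumed by the stochastic
simulation engine.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesSpec",
    "ActivatorConfig",
    "PromoterSpec",
    "NetworkModel",
    "CompiledNetwork",
    "compile_network",
    "validate",
    "build_feedback_only",
    "build_kickstart",
    "build_full_cascade",
    "DEFAULT_RATES",
]


@dataclass
class SpeciesSpec:
    """A molecular species (free-monomer pool) with first-order decay."""

    name: str
    degradation_rate: float = 0.0


@dataclass
class ActivatorConfig:
    """One way a promoter can be occupied.

    ``oligomer_order`` monomers of ``activator`` bind a free promoter copy at
    propensity ``binding_rate * C(x, n)`` (x = free monomers); while bound the
    promoter produces ``product`` at ``production_rate``; the complex
    dissociates at ``unbinding_rate``, returning all n monomers to the free
    pool.  Bound monomers are sequestered and protected from degradation.
    """

    activator: str
    oligomer_order: int
    binding_rate: float
    unbinding_rate: float
    production_rate: float
    product: str


@dataclass
class PromoterSpec:
    """A promoter with mutually exclusive activator occupancy states."""

    name: str
    activator_configs: list[ActivatorConfig] = field(default_factory=list)
    copies: int = 1
    basal_rate: float = 0.0
    basal_product: str | None = None


@dataclass
class NetworkModel:
    """Full declarative description of one regulatory-network configuration."""

    species: list[SpeciesSpec]
    promoters: list[PromoterSpec]
    label: str = "custom"

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names().index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def copy(self) -> "NetworkModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(model: NetworkModel) -> list[str]:
    """Return a list of human-readable violations; empty iff the model is valid."""
    problems: list[str] = []
    names = model.species_names()
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        problems.append(f"duplicate species names: {dupes}")
    for sp in model.species:
        if sp.degradation_rate < 0:
            problems.append(
                f"species {sp.name!r}: degradation_rate {sp.degradation_rate} < 0"
            )
    pnames = [p.name for p in model.promoters]
    if len(set(pnames)) != len(pnames):
        dupes = sorted({n for n in pnames if pnames.count(n) > 1})
        problems.append(f"duplicate promoter names: {dupes}")
    declared = set(names)
    for prom in model.promoters:
        if prom.copies < 1:
            problems.append(f"promoter {prom.name!r}: copies {prom.copies} < 1")
        if prom.basal_rate < 0:
            problems.append(f"promoter {prom.name!r}: basal_rate {prom.basal_rate} < 0")
        if prom.basal_rate > 0 and prom.basal_product not in declared:
            problems.append(
                f"promoter {prom.name!r}: basal_product {prom.basal_product!r} "
                "is not a declared species"
            )
        for cfg in prom.activator_configs:
            tag = f"promoter {prom.name!r}, activator {cfg.activator!r}"
            if cfg.activator not in declared:
                problems.append(f"{tag}: activator is not a declared species")
            if cfg.product not in declared:
                problems.append(f"{tag}: product {cfg.product!r} is not a declared species")
            if cfg.oligomer_order < 1 or int(cfg.oligomer_order) != cfg.oligomer_order:
                problems.append(f"{tag}: oligomer_order {cfg.oligomer_order} is not a positive integer")
            for rname in ("binding_rate", "unbinding_rate", "production_rate"):
                val = getattr(cfg, rname)
                if val < 0:
                    problems.append(f"{tag}: {rname} {val} < 0")
    return problems


def _require_valid(model: NetworkModel) -> NetworkModel:
    problems = validate(model)
    if problems:
        raise ValueError("invalid network model:\n  " + "\n  ".join(problems))
    return model


# ---------------------------------------------------------------------------
# Compilation to flat channel arrays
# ---------------------------------------------------------------------------

@dataclass
class CompiledNetwork:
    """Flat array view of a NetworkModel for the SSA kernel.

    Promoter copies are expanded to independent promoter slots.  Channel
    ordering is fixed and documented: for each activator config i (in promoter
    then config order) the channels [bind_i, unbind_i, produce_i]; then one
    degradation channel per species; then one basal-production channel per
    promoter slot with basal_rate > 0.
    """

    model: NetworkModel
    species_names: list[str]
    deg_rates: np.ndarray          # float64[S]
    cfg_promoter: np.ndarray       # int64[C] promoter-slot index
    cfg_activator: np.ndarray      # int64[C]
    cfg_order: np.ndarray          # int64[C]
    cfg_bind: np.ndarray           # float64[C]
    cfg_unbind: np.ndarray         # float64[C]
    cfg_rate: np.ndarray           # float64[C]
    cfg_product: np.ndarray        # int64[C]
    basal_rates: np.ndarray        # float64[P]
    basal_products: np.ndarray     # int64[P], -1 if none
    promoter_slot_names: list[str]

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_promoters(self) -> int:
        return len(self.basal_rates)

    @property
    def n_configs(self) -> int:
        return len(self.cfg_promoter)

    @property
    def n_channels(self) -> int:
        return (
            3 * self.n_configs
            + self.n_species
            + int(np.count_nonzero(self.basal_rates > 0))
        )

    def channel_labels(self) -> list[str]:
        """Labels for the kernel's full channel enumeration.

        The kernel enumerates 3*C config channels, then one degradation slot
        per species and one basal slot per promoter; slots with rate 0 are
        structurally inert (propensity identically zero) and are excluded
        from :attr:`n_channels`, which counts reactions that can fire.
        """
        labels = []
        for i in range(self.n_configs):
            prom = self.promoter_slot_names[self.cfg_promoter[i]]
            act = self.species_names[self.cfg_activator[i]]
            labels += [f"bind:{prom}:{act}", f"unbind:{prom}:{act}", f"produce:{prom}:{act}"]
        for s in self.species_names:
            labels.append(f"degrade:{s}")
        for p in range(self.n_promoters):
            labels.append(f"basal:{self.promoter_slot_names[p]}")
        return labels


def compile_network(model: NetworkModel) -> CompiledNetwork:
    """Lower a validated NetworkModel to flat reaction-channel arrays."""
    _require_valid(model)
    names = model.species_names()
    deg = np.array([s.degradation_rate for s in model.species], dtype=np.float64)

    cfg_promoter, cfg_activator, cfg_order = [], [], []
    cfg_bind, cfg_unbind, cfg_rate, cfg_product = [], [], [], []
    basal_rates, basal_products, slot_names = [], [], []

    slot = 0
    for prom in model.promoters:
        for c in range(prom.copies):
            slot_name = prom.name if prom.copies == 1 else f"{prom.name}#{c}"
            slot_names.append(slot_name)
            basal_rates.append(prom.basal_rate)
            basal_products.append(
                names.index(prom.basal_product) if prom.basal_product else -1
            )
            for cfg in prom.activator_configs:
                cfg_promoter.append(slot)
                cfg_activator.append(names.index(cfg.activator))
                cfg_order.append(int(cfg.oligomer_order))
                cfg_bind.append(cfg.binding_rate)
                cfg_unbind.append(cfg.unbinding_rate)
                cfg_rate.append(cfg.production_rate)
                cfg_product.append(names.index(cfg.product))
            slot += 1

    return CompiledNetwork(
        model=model,
        species_names=names,
        deg_rates=deg,
        cfg_promoter=np.array(cfg_promoter, dtype=np.int64),
        cfg_activator=np.array(cfg_activator, dtype=np.int64),
        cfg_order=np.array(cfg_order, dtype=np.int64),
        cfg_bind=np.array(cfg_bind, dtype=np.float64),
        cfg_unbind=np.array(cfg_unbind, dtype=np.float64),
        cfg_rate=np.array(cfg_rate, dtype=np.float64),
        cfg_product=np.array(cfg_product, dtype=np.int64),
        basal_rates=np.array(basal_rates, dtype=np.float64),
        basal_products=np.array(basal_products, dtype=np.int64),
        promoter_slot_names=slot_names,
    )


# ---------------------------------------------------------------------------
# Preset builders
# ---------------------------------------------------------------------------

#: Shipped default rate constants (arbitrary time unit).  A-prefixed rates
#: attach to the BisDC/P_alpA feedback node, B-prefixed to BisR acting on
#: P_alpA, T-prefixed to TciR acting on P_bisR, C5 is the cascade production
#: rate at P_bisR, L-prefixed rates to the BisDC-dependent late node.  Values
#: were fixed once by the calibration procedure in analysis/00_calibrate.py
#: (bimodal feedback output from a binomial mean-8 start; full-cascade
#: positive fraction inside the empirically observed 3-5% tc-cell range).
DEFAULT_RATES: dict[str, float] = {
    # BisDC autoregulatory feedback node (P_alpA)
    "A1": 0.01,   # BisDC oligomer binding to P_alpA
    "A2": 1.0,    # unbinding
    "A3": 10.0,   # BisDC production while P_alpA is bound
    "A4": 0.1,    # BisDC degradation
    "n": 2,       # activator oligomer order (all nodes)
    # BisR kickstart of P_alpA
    "B1": 0.01,   # BisR oligomer binding to P_alpA
    "B2": 1.0,    # unbinding
    "B4": 0.02,   # BisR degradation
    # TciR -> P_bisR cascade node
    "T1": 0.0008, # TciR oligomer binding to P_bisR
    "T2": 1.0,    # unbinding
    "T4": 0.3,    # TciR degradation
    "C5": 40.0,   # BisR production while P_bisR is bound
    # BisDC-dependent late node (P_late)
    "L1": 0.01,   # BisDC oligomer binding to P_late
    "L2": 1.0,    # unbinding
    "L3": 10.0,   # late-protein production while bound
    "L4_stable": 0.02,
    "L4_unstable": 0.1,
}


def _merged(params: dict | None) -> dict:
    rates = dict(DEFAULT_RATES)
    if params:
        unknown = set(params) - set(rates)
        if unknown:
            raise ValueError(f"unknown rate parameters: {sorted(unknown)}")
        rates.update(params)
    n = rates["n"]
    if n < 1 or int(n) != n:
        raise ValueError(f"oligomer order n must be a positive integer, got {n}")
    rates["n"] = int(n)
    return rates


def build_feedback_only(params: dict | None = None) -> NetworkModel:
    """Bare BisDC autoregulatory loop: BisDC binds P_alpA and produces itself.

    Compiles to exactly four channels (bind, unbind, produce, degrade).
    """
    r = _merged(params)
    model = NetworkModel(
        species=[SpeciesSpec("BisDC", degradation_rate=r["A4"])],
        promoters=[
            PromoterSpec(
                "P_alpA",
                activator_configs=[
                    ActivatorConfig("BisDC", r["n"], r["A1"], r["A2"], r["A3"], "BisDC")
                ],
            )
        ],
        label="feedback_only",
    )
    return _require_valid(model)


def build_kickstart(params: dict | None = None, include_feedback: bool = True) -> NetworkModel:
    """BisR pulse kickstarting the BisDC feedback loop.

    BisR has no production channel: it enters as an initial copy-number pulse
    and only degrades.  P_alpA carries two mutually exclusive activator
    configurations (BisR-bound, BisDC-bound), both producing BisDC.
    """
    r = _merged(params)
    configs = [ActivatorConfig("BisR", r["n"], r["B1"], r["B2"], r["A3"], "BisDC")]
    if include_feedback:
        configs.append(ActivatorConfig("BisDC", r["n"], r["A1"], r["A2"], r["A3"], "BisDC"))
    model = NetworkModel(
        species=[
            SpeciesSpec("BisR", degradation_rate=r["B4"]),
            SpeciesSpec("BisDC", degradation_rate=r["A4"]),
        ],
        promoters=[PromoterSpec("P_alpA", activator_configs=configs)],
        label="kickstart" if include_feedback else "kickstart_nofb",
    )
    return _require_valid(model)


def build_full_cascade(
    params: dict | None = None,
    include_feedback: bool = True,
    include_late: bool = False,
    late_stability: str = "stable",
) -> NetworkModel:
    """Complete TciR -> BisR -> BisDC cascade, optionally with a late gene.

    TciR has no production channel (initial distribution only); it drives
    BisR production from P_bisR at rate C5.  P_alpA is as in
    :func:`build_kickstart`.  With ``include_late`` a BisDC-activated P_late
    produces a late protein whose degradation rate is selected by
    ``late_stability`` ("stable": low turnover; "unstable": high turnover).
    """
    r = _merged(params)
    if late_stability not in ("stable", "unstable"):
        raise ValueError(f"late_stability must be 'stable' or 'unstable', got {late_stability!r}")
    species = [
        SpeciesSpec("TciR", degradation_rate=r["T4"]),
        SpeciesSpec("BisR", degradation_rate=r["B4"]),
        SpeciesSpec("BisDC", degradation_rate=r["A4"]),
    ]
    alpA_configs = [ActivatorConfig("BisR", r["n"], r["B1"], r["B2"], r["A3"], "BisDC")]
    if include_feedback:
        alpA_configs.append(ActivatorConfig("BisDC", r["n"], r["A1"], r["A2"], r["A3"], "BisDC"))
    promoters = [
        PromoterSpec(
            "P_bisR",
            activator_configs=[
                ActivatorConfig("TciR", r["n"], r["T1"], r["T2"], r["C5"], "BisR")
            ],
        ),
        PromoterSpec("P_alpA", activator_configs=alpA_configs),
    ]
    label = "full_cascade" if include_feedback else "full_cascade_nofb"
    if include_late:
        l4 = r["L4_stable"] if late_stability == "stable" else r["L4_unstable"]
        species.append(SpeciesSpec("Late", degradation_rate=l4))
        promoters.append(
            PromoterSpec(
                "P_late",
                activator_configs=[
                    ActivatorConfig("BisDC", r["n"], r["L1"], r["L2"], r["L3"], "Late")
                ],
            )
        )
        label += f"_late_{late_stability}"
    model = NetworkModel(species=species, promoters=promoters, label=label)
    return _require_valid(model)


PRESETS = {
    "feedback": build_feedback_only,
    "kickstart": build_kickstart,
    "cascade": build_full_cascade,
}
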