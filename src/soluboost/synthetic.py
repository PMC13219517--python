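"""Synthetic solubility-corpus generator.

Generates corpora with the statistical and thermodynamic structure the model
assumes, so that every other module is testable without any experimental
download.  The generative model is

    ln x(solute, solvent, T) = ln x_id(solute, T) − ln γ(solute, solvent, T) + ε

with three ingredients:

* **Ideal solubility** from pure-solute melting properties, with the linear
  heat-capacity correction ΔCp(T) = q + r·(T − Tm):

      ln x_id = −(ΔHfus/R)(1/T − 1/Tm)
                − (1/R)[(q − r·Tm)·ln(Tm/T) + r·(Tm − T)]
                + (1/(R·T))[q·(Tm − T) − r·(Tm − T)²/2]

  (ΔHfus converted to J/mol; R the molar gas constant).  It is 0 at T = Tm
  (x_id = 1) and reduces to the van't Hoff form when q = r = 0.

* **Activity penalty** ln γ = κ·m·(Tm/T) ≥ 0, where the mismatch m between
  solute and solvent is a descriptor distance: per solute, anchor values
  (ε*, T_b*) are drawn once from the seeded stream inside the solvent
  descriptor ranges, and m = ½|ε − ε*|/Δε + ½|T_b − T_b*|/ΔT_b with Δε, ΔT_b
  the solvent-table spans.  Positive κ·m makes ln γ strictly decreasing in
  T, so the noise-free ln x is strictly increasing in T (sub-ideal
  solubility, never above x_id ≤ 1).

* **Noise** ε ~ N(0, σ²) on ln x (multiplicative on x: experimental
  solubility scatter is relative).  ln x is clamped to ≤ 0 so x stays a
  valid mole fraction.

Defaults emulate the corpus the model targets: the five packaged solutes in
their tabulated solvent pairings (30 solute–solvent systems), 8 evenly
spaced temperatures in 278–323 K per pair, κ = 4 (spreading x over several
orders of magnitude across pairs) and σ = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import R as GAS_CONSTANT

from .data_model import (
    Corpus,
    SolubilityRecord,
    SoluteDescriptors,
    SolventDescriptors,
    normalize_name,
    packaged_solutes,
    packaged_solvents,
)

__all__ = [
    "DEFAULT_SYSTEMS",
    "GeneratorConfig",
    "ideal_log_solubility",
    "activity_correction",
    "solute_anchors",
    "generate_corpus",
]

#: Tabulated solute → solvents pairing (30 binary systems).
DEFAULT_SYSTEMS: dict[str, tuple[str, ...]] = {
    "butyl paraben": ("methanol", "ethyl acetate", "ethanol", "1-propanol",
                      "acetonitrile", "acetone"),
    "fenoxycarb": ("methanol", "toluene", "ethanol", "2-propanol", "ethyl acetate"),
    "fenofibrate": ("methanol", "ethyl acetate", "ethanol", "1-propanol",
                    "2-propanol", "acetonitrile"),
    "risperidone": ("methanol", "toluene", "ethanol", "1-propanol", "2-propanol",
                    "1-butanol", "acetone", "ethyl acetate"),
    "butamben": ("methanol", "1-propanol", "2-propanol", "1-butanol", "toluene"),
}


def ideal_log_solubility(solute: SoluteDescriptors, T) -> float | np.ndarray:
    """ln x_id: heat-capacity-corrected ideal mole-fraction solubility.

    Closed form of the melting-property integral with ΔCp linear in T.
    Requires 0 < T ≤ Tm; returns 0 at the melting point.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    if np.any(T > solute.Tm):
        raise ValueError(f"T exceeds the melting point {solute.Tm} K of {solute.name}")
    Tm, q, r = solute.Tm, solute.q, solute.r
    dH = solute.dHfus * 1000.0  # kJ/mol → J/mol
    dT = Tm - T
    out = (
        -(dH / GAS_CONSTANT) * (1.0 / T - 1.0 / Tm)
        - ((q - r * Tm) * np.log(Tm / T) + r * dT) / GAS_CONSTANT
        + (q * dT - 0.5 * r * dT**2) / (GAS_CONSTANT * T)
    )
    return float(out) if out.ndim == 0 else out


def solute_anchors(solutes, solvents, rng: np.random.Generator) -> dict:
    """Draw per-solute descriptor anchors (ε*, T_b*) inside the solvent ranges.

    Drawn once per solute, in sorted-name order, so the result is a pure
    function of the stream state.  Returns {name: (eps_star, bp_star)}.
    """
    eps = np.array([s.dielectric for s in solvents])
    bps = np.array([s.bp for s in solvents])
    anchors = {}
    for sol in sorted(solutes, key=lambda s: normalize_name(s.name)):
        anchors[normalize_name(sol.name)] = (
            float(rng.uniform(eps.min(), eps.max())),
            float(rng.uniform(bps.min(), bps.max())),
        )
    return anchors


def activity_correction(solute: SoluteDescriptors, solvent: SolventDescriptors,
                        T: float, kappa: float, anchor: tuple[float, float],
                        spans: tuple[float, float]) -> float:
    """ln γ = κ·m·(Tm/T) ≥ 0 with descriptor-mismatch m ∈ [0, ~1].

    ``anchor`` is the solute's (ε*, T_b*) pair; ``spans`` the (Δε, ΔT_b)
    normalizers from the solvent table.  Strictly decreasing in T whenever
    κ·m > 0.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    d_eps, d_bp = spans
    m = 0.5 * abs(solvent.dielectric - anchor[0]) / d_eps + 0.5 * abs(solvent.bp - anchor[1]) / d_bp
    return kappa * m * (solute.Tm / T)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    ``systems`` maps solute name → solvent names; ``None`` uses the packaged
    30-system pairing restricted to the configured solutes/solvents.
    Temperatures are ``n_temperatures`` evenly spaced points in
    [t_min, t_max] for every pair and must stay below every solute's Tm.
    """

    solutes: list[SoluteDescriptors] = field(default_factory=lambda: list(packaged_solutes().values()))
    solvents: list[SolventDescriptors] = field(default_factory=lambda: list(packaged_solvents().values()))
    systems: dict[str, tuple[str, ...]] | None = None
    t_min: float = 278.0
    t_max: float = 323.0
    n_temperatures: int = 8
    kappa: float = 4.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0 or self.sigma < 0:
            raise ValueError("kappa and sigma must be nonnegative")
        if not (0 < self.t_min <= self.t_max):
            raise ValueError("need 0 < t_min <= t_max")
        tm_min = min(s.Tm for s in self.solutes)
        if self.t_max >= tm_min:
            raise ValueError(
                f"temperature grid must stay below the lowest melting point ({tm_min} K)")
        if self.n_temperatures < 1:
            raise ValueError("need at least one temperature")

    def resolved_systems(self) -> dict[str, tuple[str, ...]]:
        solute_names = {normalize_name(s.name) for s in self.solutes}
        solvent_names = {normalize_name(s.name) for s in self.solvents}
        if self.systems is not None:
            table = {normalize_name(k): tuple(normalize_name(v) for v in vs)
                     for k, vs in self.systems.items()}
        else:
            table = {k: vs for k, vs in DEFAULT_SYSTEMS.items() if k in solute_names}
            # solutes outside the packaged pairing get every configured solvent
            for name in sorted(solute_names.difference(table)):
                table[name] = tuple(sorted(solvent_names))
        for solute, solvs in table.items():
            if solute not in solute_names:
                raise KeyError(f"system names unknown solute {solute!r}")
            for sv in solvs:
                if normalize_name(sv) not in solvent_names:
                    raise KeyError(f"system names unknown solvent {sv!r}")
        return table


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate one corpus; fully reproducible from ``config.seed``.

    With σ = 0 every pair's solubility is strictly increasing in T (sum of
    the increasing ideal term and the increasing −ln γ term).
    """
    rng = np.random.default_rng(config.seed)
    solutes = {normalize_name(s.name): s for s in config.solutes}
    solvents = {normalize_name(s.name): s for s in config.solvents}
    anchors = solute_anchors(config.solutes, config.solvents, rng)
    eps = np.array([s.dielectric for s in config.solvents])
    bps = np.array([s.bp for s in config.solvents])
    spans = (float(eps.max() - eps.min()) or 1.0, float(bps.max() - bps.min()) or 1.0)
    temperatures = np.linspace(config.t_min, config.t_max, config.n_temperatures)

    records = []
    systems = config.resolved_systems()
    for solute_name in sorted(systems):
        sol = solutes[solute_name]
        for solvent_name in sorted(normalize_name(v) for v in systems[solute_name]):
            solv = solvents[solvent_name]
            for T in temperatures:
                ln_x = ideal_log_solubility(sol, T) - activity_correction(
                    sol, solv, float(T), config.kappa, anchors[solute_name], spans)
                if config.sigma > 0:
                    ln_x += config.sigma * rng.standard_normal()
                ln_x = min(ln_x, 0.0)  # keep x a valid mole fraction
                records.append(SolubilityRecord(sol.name, solv.name, float(T), float(np.exp(ln_x))))
    return Corpus(records, solutes, solvents)
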