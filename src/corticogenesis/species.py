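"""Species-level parameterizations of cortical neurogenesis.

A :class:`SpeciesParams` bundles the constants that characterize one
species' window of cortical neurogenesis: its timing (onset ``t0``, end
``tF``, and the deeper-layer completion time ``tM``), the deeper-layer
neuron fraction ``phi``, the adult neocortical neuron count, and the
demographic corrections (post-neurogenesis neuronal death, interneuron
immigration) used when converting adult counts into a neurogenic-output
target.

A registry for mouse, macaque and human ships with the package as a YAML
data file; :func:`load_species` reads it and :func:`load_config` merges a
user configuration file on top of a registered base species.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "SpeciesParams",
    "SpeciesLookupError",
    "ConfigError",
    "load_species",
    "registered_species",
    "species_cell_cycle_data",
    "reference_strategy",
    "load_config",
    "save_config",
]

DEFAULT_DEATH_FRACTION = 0.30
DEFAULT_MIGRATION_FRACTION = 0.25


class SpeciesLookupError(KeyError):
    """Raised when a species name is not in the registry."""


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or violates invariants."""


@dataclass(frozen=True)
class SpeciesParams:
    """Constants describing one species' cortical neurogenesis.

    Attributes
    ----------
    name:
        Species identifier (e.g. ``"mouse"``).
    t0, tF:
        Embryonic days of neurogenesis onset and end. Continuous axis;
        half days such as E14.5 are legal.
    tM:
        Embryonic day at which deeper-layer (V/VI) production completes
        and layer IV production starts; must satisfy ``t0 < tM < tF``.
    phi:
        Fraction of the final neuron count residing in deeper layers,
        in (0, 1).
    N_adult:
        Adult neocortical neuron count (cells).
    P0_literature:
        Literature estimate of the founder progenitor population, if any.
    death_fraction:
        Fraction of locally produced neurons lost to post-neurogenesis
        cell death (default 0.30).
    migration_fraction:
        Fraction of adult cortical neurons that immigrated (interneurons;
        default 0.25).
    """

    name: str
    t0: float
    tF: float
    tM: float
    phi: float
    N_adult: float
    P0_literature: Optional[float] = None
    death_fraction: float = DEFAULT_DEATH_FRACTION
    migration_fraction: float = DEFAULT_MIGRATION_FRACTION

    def __post_init__(self) -> None:
        if not (self.t0 < self.tM < self.tF):
            raise ConfigError(
                f"{self.name}: require t0 < tM < tF, "
                f"got t0={self.t0}, tM={self.tM}, tF={self.tF}"
            )
        if not 0.0 < self.phi < 1.0:
            raise ConfigError(f"{self.name}: phi must lie in (0, 1), got {self.phi}")
        if not 0.0 <= self.death_fraction < 1.0:
            raise ConfigError(
                f"{self.name}: death_fraction must lie in [0, 1), "
                f"got {self.death_fraction}"
            )
        if not 0.0 <= self.migration_fraction < 1.0:
            raise ConfigError(
                f"{self.name}: migration_fraction must lie in [0, 1), "
                f"got {self.migration_fraction}"
            )
        if self.N_adult <= 0:
            raise ConfigError(f"{self.name}: N_adult must be positive, got {self.N_adult}")
        if self.P0_literature is not None and self.P0_literature <= 0:
            raise ConfigError(
                f"{self.name}: P0_literature must be positive, got {self.P0_literature}"
            )

    @property
    def window(self) -> tuple[float, float]:
        """The neurogenesis window ``(t0, tF)``."""
        return (self.t0, self.tF)

    def with_overrides(self, **overrides) -> "SpeciesParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)


_FIELD_NAMES = (
    "name",
    "t0",
    "tF",
    "tM",
    "phi",
    "N_adult",
    "P0_literature",
    "death_fraction",
    "migration_fraction",
)


def _registry() -> dict:
    text = resources.files("corticogenesis.data").joinpath("species.yaml").read_text()
    return yaml.safe_load(text)


def registered_species() -> list[str]:
    """Names of the species packaged with the registry."""
    return sorted(_registry())


def load_species(name: str) -> SpeciesParams:
    """Look up a registered species by name.

    Raises
    ------
    SpeciesLookupError
        If ``name`` is not one of :func:`registered_species`.
    """
    reg = _registry()
    if name not in reg:
        raise SpeciesLookupError(
            f"unknown species {name!r}; registered: {', '.join(sorted(reg))}"
        )
    entry = {k: v for k, v in reg[name].items() if k not in ("cell_cycle", "strategies")}
    return SpeciesParams(name=name, **entry)


def species_cell_cycle_data(name: str) -> dict:
    """Packaged cell-cycle measurements for a registered species.

    Returns a dict with keys ``constant_hours`` (the average cell-cycle
    length) and ``anchors`` (a list of ``(embryonic day, hours)`` pairs).
    """
    reg = _registry()
    if name not in reg:
        raise SpeciesLookupError(
            f"unknown species {name!r}; registered: {', '.join(sorted(reg))}"
        )
    cc = reg[name]["cell_cycle"]
    return {
        "constant_hours": float(cc["constant_hours"]),
        "anchors": [(float(d), float(h)) for d, h in cc["anchors"]],
    }


def reference_strategy(name: str, mode: str = "constant", tc_scale: float = 1.0):
    """The packaged reference division strategy for a species.

    These are the literature strategy 4-tuples (alpha0, alphaS, betaF, tS)
    characterizing each species under the given cell-cycle model (and,
    for the human age-dependent variants, cell-cycle scaling). They are
    the default parameterization for founder-population estimation; an
    exhaustive refit via :func:`corticogenesis.search.fit_strategy` is
    the alternative (see the methods documentation on why the refit is
    not uniquely determined).

    Raises
    ------
    SpeciesLookupError
        Unknown species, or no strategy packaged for this mode/scale.
    """
    from .strategy import Strategy

    reg = _registry()
    if name not in reg:
        raise SpeciesLookupError(
            f"unknown species {name!r}; registered: {', '.join(sorted(reg))}"
        )
    entries = reg[name].get("strategies", {}).get(mode, [])
    for entry in entries:
        if abs(float(entry["tc_scale"]) - tc_scale) < 1e-9:
            return Strategy.from_sequence(entry["strategy"])
    raise SpeciesLookupError(
        f"no reference strategy packaged for {name!r} with mode={mode!r}, "
        f"tc_scale={tc_scale}"
    )


def load_config(path: str | Path) -> SpeciesParams:
    """Read a YAML configuration file into a validated :class:`SpeciesParams`.

    The file either names a base species to start from::

        species: human
        death_fraction: 0.8

    or spells out every field from scratch (``name`` plus the timing,
    phi and N_adult fields). Unknown keys and invariant violations are
    reported with the offending field name.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a key/value mapping at top level")

    base_name = raw.pop("species", None)
    unknown = set(raw) - set(_FIELD_NAMES)
    if unknown:
        raise ConfigError(f"{path}: unknown field(s): {', '.join(sorted(unknown))}")

    if base_name is not None:
        base = load_species(base_name)
        return base.with_overrides(**raw)
    missing = {"name", "t0", "tF", "tM", "phi", "N_adult"} - set(raw)
    if missing:
        raise ConfigError(
            f"{path}: no base 'species' given and required field(s) missing: "
            f"{', '.join(sorted(missing))}"
        )
    return SpeciesParams(**raw)


def save_config(params: SpeciesParams, path: str | Path) -> Path:
    """Write a SpeciesParams to YAML such that :func:`load_config` round-trips."""
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(params), sort_keys=False))
    return path
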