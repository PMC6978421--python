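"""Run configuration and species presets.

Presets carry the published population parameters (mean ± SD) for the two
species with printed values: M. smegmatis (lag 2.9 ± 0.8 h, interdivision
3.6 ± 0.7 h, speeds 0.15 ± 0.06 and 0.61 ± 0.13 µm/h) and M. tuberculosis
(lag 6.2 ± 2.2 h, interdivision 16.3 ± 3.1 h; elongation speeds are not
published for M. tuberculosis, so the M. smegmatis speeds are used). Other
species are supported through a custom PopulationParams block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .model import PopulationParams

__all__ = ["RunConfig", "SPECIES_PRESETS", "population_for"]

SPECIES_PRESETS: dict[str, PopulationParams] = {
    "smegmatis": PopulationParams(
        lag_mean_h=2.9, lag_sd_h=0.8, interdiv_mean_h=3.6, interdiv_sd_h=0.7,
        v_slow_mean=0.15, v_slow_sd=0.06, v_fast_mean=0.61, v_fast_sd=0.13,
    ),
    "tuberculosis": PopulationParams(
        lag_mean_h=6.2, lag_sd_h=2.2, interdiv_mean_h=16.3, interdiv_sd_h=3.1,
        v_slow_mean=0.15, v_slow_sd=0.06, v_fast_mean=0.61, v_fast_sd=0.13,
    ),
}


@dataclass
class RunConfig:
    """Configuration for the CLI commands; loadable from YAML."""

    seed: int
    species: str = "smegmatis"
    custom_population: PopulationParams | None = None
    n_poles: int = 20
    dt_h: float = 13.0 / 60.0
    duration_h: float = 6.0
    sigma_um: float = 0.05
    pixel_size_nm: float = 30.0
    snap_nm: float = 100.0
    noise_sigma: float = 0.02
    division_threshold_factor: float = 3.0
    model_selection_margin: float = 2.0
    extras: dict = field(default_factory=dict)

    def population(self) -> PopulationParams:
        return population_for(self.species, self.custom_population)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic commands "
                             "require reproducibility)")
        custom = raw.pop("custom_population", None)
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(custom_population=PopulationParams(**custom) if custom else None,
                  extras=extras, **kwargs)
        _ = cfg.population()   # fail fast on unknown preset
        return cfg


def population_for(species: str,
                   custom: PopulationParams | None = None) -> PopulationParams:
    if species == "custom":
        if custom is None:
            raise ValueError("species 'custom' requires a custom_population block")
        return custom
    try:
        return SPECIES_PRESETS[species]
    except KeyError:
        valid = ", ".join(sorted(SPECIES_PRESETS) + ["custom"])
        raise ValueError(
            f"unknown species preset {species!r}; valid presets: {valid}"
        ) from None
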