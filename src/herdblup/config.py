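"""Structured configuration for simulation and study runs.

Configs are single YAML files with ``simulate`` and/or ``study`` sections.
Validation is strict: unknown keys are rejected by name and all schema problems
are reported together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .hys import SEASON_RULES
from .mme import VarianceComponents

__all__ = [
    "ConfigError",
    "CountrySimConfig",
    "SimConfig",
    "CountryData",
    "StudyConfig",
    "read_config",
    "write_config",
    "default_sim_config",
    "paper_scale_config",
    "desk_scale_config",
    "default_varcomp",
]

TRAITS = ["my305", "afc", "ci1"]


class ConfigError(ValueError):
    """Aggregated schema violations; message lists every problem found."""


# ---------------------------------------------------------------------------
# default truth/analysis parameters (declared assumptions of the simulator)
# ---------------------------------------------------------------------------

#: genetic SDs (trait units) for the default truth: MY305 kg, AFC months, CI1 months
DEFAULT_SIGMA_G = {"my305": 528.0, "afc": 61.19, "ci1": 20.29}
#: default heritabilities
DEFAULT_H2 = {"my305": 0.25, "afc": 0.15, "ci1": 0.08}
#: default genetic correlations
DEFAULT_RG = {("my305", "afc"): -0.2, ("my305", "ci1"): 0.2, ("afc", "ci1"): 0.1}
#: default residual correlations (uniform, modest)
DEFAULT_RE = 0.1


def default_varcomp(sigma_g: dict[str, float] | None = None,
                    h2: dict[str, float] | None = None) -> VarianceComponents:
    """Build the default G0/R0 from genetic SDs, heritabilities and correlations."""
    sigma_g = sigma_g or DEFAULT_SIGMA_G
    h2 = h2 or DEFAULT_H2
    t = len(TRAITS)
    g_sd = np.array([sigma_g[x] for x in TRAITS])
    e_sd = np.array([sigma_g[x] * np.sqrt((1 - h2[x]) / h2[x]) for x in TRAITS])
    G0 = np.outer(g_sd, g_sd)
    R0 = np.outer(e_sd, e_sd)
    for i in range(t):
        for j in range(t):
            if i != j:
                key = (TRAITS[min(i, j)], TRAITS[max(i, j)])
                G0[i, j] *= DEFAULT_RG[key]
                R0[i, j] *= DEFAULT_RE
    return VarianceComponents(list(TRAITS), G0, R0)


@dataclass
class CountrySimConfig:
    name: str
    n_sires: int
    n_dams: int
    n_cows: int
    n_herds: int
    year_start: int
    year_end: int

    def validate(self, errors: list[str]) -> None:
        for f in ("n_sires", "n_dams", "n_cows", "n_herds"):
            if getattr(self, f) <= 0:
                errors.append(f"countries[{self.name}].{f} must be positive")
        if self.year_end < self.year_start:
            errors.append(f"countries[{self.name}]: year_end before year_start")


@dataclass
class SimConfig:
    countries: list[CountrySimConfig]
    n_common_sires: int = 0
    seed: int = 0
    sire_usage: str = "geometric"  # skewed daughters-per-sire, AI-style; or "uniform"
    season_rule: str = "quarter"
    age_mean: float = 30.0
    age_sd: float = 3.0
    country_mean: dict = field(default_factory=dict)   # country -> trait -> mean
    herd_sd: dict = field(default_factory=lambda: {"my305": 300.0, "afc": 6.0, "ci1": 3.0})
    hys_sd: dict = field(default_factory=lambda: {"my305": 150.0, "afc": 3.0, "ci1": 1.5})
    age_slope: dict = field(default_factory=lambda: {"my305": 15.0, "afc": 0.0, "ci1": 0.1})
    missing_rates: dict = field(default_factory=lambda: {"my305": 0.0, "afc": 0.15, "ci1": 0.25})
    varcomp: VarianceComponents = field(default_factory=default_varcomp)

    def validate(self) -> None:
        errors: list[str] = []
        if not self.countries:
            errors.append("simulate.countries must be non-empty")
        names = [c.name for c in self.countries]
        if len(set(names)) != len(names):
            errors.append("duplicate country names")
        for c in self.countries:
            c.validate(errors)
        if self.countries and self.n_common_sires > min(c.n_sires for c in self.countries):
            errors.append("n_common_sires exceeds the smallest country's n_sires")
        if self.n_common_sires < 0:
            errors.append("n_common_sires must be >= 0")
        if self.season_rule not in SEASON_RULES:
            errors.append(f"unknown season_rule {self.season_rule!r}")
        if self.sire_usage not in ("geometric", "uniform"):
            errors.append(f"unknown sire_usage {self.sire_usage!r}")
        for rname, rates in (("missing_rates", self.missing_rates),):
            for t, v in rates.items():
                if not 0 <= v <= 1:
                    errors.append(f"{rname}[{t}] must be in [0,1]")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class CountryData:
    name: str
    pedigree: str
    performance: str


@dataclass
class StudyConfig:
    countries: list[CountryData]
    varcomp: VarianceComponents
    seed: int = 0
    shared_sires: str | None = None
    namespace_ids: bool = True
    season_rule: str = "quarter"
    scenarios: list[int] = field(default_factory=lambda: [5, 10, 25, 50, 75, 100])
    pooled_n_rule: str = "sum"  # pooled candidate count: summed sire lists, or "dedup"
    accuracy_mode: str = "mean_all"
    out_dir: str = "."

    def validate(self) -> None:
        errors: list[str] = []
        if len(self.countries) < 2:
            errors.append("study needs at least two countries for the pooled run")
        if any(k <= 0 for k in self.scenarios):
            errors.append("scenario k values must be positive")
        if self.season_rule not in SEASON_RULES:
            errors.append(f"unknown season_rule {self.season_rule!r}")
        if self.pooled_n_rule not in ("sum", "dedup"):
            errors.append(f"unknown pooled_n_rule {self.pooled_n_rule!r}")
        if self.accuracy_mode not in ("mean_all", "mean_top_k"):
            errors.append(f"unknown accuracy_mode {self.accuracy_mode!r}")
        if errors:
            raise ConfigError("; ".join(errors))


# ---------------------------------------------------------------------------
# YAML (de)serialization with strict key checking
# ---------------------------------------------------------------------------

_SIM_KEYS = {"countries", "n_common_sires", "seed", "sire_usage", "season_rule",
             "age_mean", "age_sd", "country_mean", "herd_sd", "hys_sd", "age_slope",
             "missing_rates", "varcomp"}
_COUNTRY_SIM_KEYS = {"name", "n_sires", "n_dams", "n_cows", "n_herds",
                     "year_start", "year_end"}
_STUDY_KEYS = {"countries", "varcomp", "seed", "shared_sires", "namespace_ids",
               "season_rule", "scenarios", "pooled_n_rule", "accuracy_mode", "out_dir"}
_COUNTRY_DATA_KEYS = {"name", "pedigree", "performance"}
_VARCOMP_KEYS = {"traits", "G0", "R0"}


def _check_keys(section: str, data: dict, allowed: set, errors: list[str]) -> None:
    unknown = set(data) - allowed
    for k in sorted(unknown):
        errors.append(f"unknown key {k!r} in {section}")


def _varcomp_from_dict(data: dict, section: str, errors: list[str]):
    _check_keys(section, data, _VARCOMP_KEYS, errors)
    try:
        return VarianceComponents(list(data["traits"]),
                                  np.array(data["G0"], dtype=float),
                                  np.array(data["R0"], dtype=float))
    except (KeyError, ValueError, TypeError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def _varcomp_to_dict(vc: VarianceComponents) -> dict:
    return {"traits": list(vc.traits), "G0": vc.G0.tolist(), "R0": vc.R0.tolist()}


def read_config(path) -> dict:
    """Read a YAML config; returns {'simulate': SimConfig?, 'study': StudyConfig?}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    _check_keys("(root)", raw, {"simulate", "study"}, errors)
    out: dict = {}
    if "simulate" in raw:
        out["simulate"] = _sim_from_dict(raw["simulate"], errors)
    if "study" in raw:
        out["study"] = _study_from_dict(raw["study"], errors)
    if errors:
        raise ConfigError("; ".join(errors))
    for cfg in out.values():
        cfg.validate()
    return out


def _sim_from_dict(data: dict, errors: list[str]) -> SimConfig | None:
    _check_keys("simulate", data, _SIM_KEYS, errors)
    countries = []
    for c in data.get("countries", []):
        _check_keys("simulate.countries[]", c, _COUNTRY_SIM_KEYS, errors)
        try:
            countries.append(CountrySimConfig(**{k: c[k] for k in _COUNTRY_SIM_KEYS & set(c)}))
        except TypeError as exc:
            errors.append(f"simulate.countries[]: {exc}")
    kwargs = {k: data[k] for k in _SIM_KEYS & set(data)
              if k not in ("countries", "varcomp")}
    vc = (_varcomp_from_dict(data["varcomp"], "simulate.varcomp", errors)
          if "varcomp" in data else default_varcomp())
    if errors:
        return None
    return SimConfig(countries=countries, varcomp=vc, **kwargs)


def _study_from_dict(data: dict, errors: list[str]) -> StudyConfig | None:
    _check_keys("study", data, _STUDY_KEYS, errors)
    countries = []
    for c in data.get("countries", []):
        _check_keys("study.countries[]", c, _COUNTRY_DATA_KEYS, errors)
        try:
            countries.append(CountryData(**{k: c[k] for k in _COUNTRY_DATA_KEYS & set(c)}))
        except TypeError as exc:
            errors.append(f"study.countries[]: {exc}")
    if "varcomp" not in data:
        errors.append(
            "study.varcomp missing: supply genetic/residual components or estimate "
            "them with the reml subcommand — there is no silent default"
        )
        vc = None
    else:
        vc = _varcomp_from_dict(data["varcomp"], "study.varcomp", errors)
    kwargs = {k: data[k] for k in _STUDY_KEYS & set(data)
              if k not in ("countries", "varcomp")}
    if errors:
        return None
    return StudyConfig(countries=countries, varcomp=vc, **kwargs)


def write_config(cfgs: dict, path) -> None:
    """Write SimConfig/StudyConfig objects back to YAML (round-trips with read_config)."""
    raw: dict = {}
    if "simulate" in cfgs:
        sim = cfgs["simulate"]
        d = asdict(sim)
        d["varcomp"] = _varcomp_to_dict(sim.varcomp)
        raw["simulate"] = d
    if "study" in cfgs:
        st = cfgs["study"]
        d = asdict(st)
        d["varcomp"] = _varcomp_to_dict(st.varcomp)
        raw["study"] = d
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

DEFAULT_COUNTRY_MEANS = {
    "KE": {"my305": 3500.0, "afc": 34.0, "ci1": 14.0},
    "SA": {"my305": 6500.0, "afc": 28.0, "ci1": 13.0},
}


def default_sim_config(**overrides) -> SimConfig:
    """Desk-scale two-country default used throughout the test-bed."""
    return desk_scale_config(**overrides)


def paper_scale_config(seed: int = 0) -> SimConfig:
    """The published herdbook sizes: 2,333 / 25,208 recorded cows, 103 / 505 sires
    with daughter records in Kenya / South Africa, 40 shared sires, Kenyan records
    spanning 1979–2014 and South African 1997–2014."""
    return SimConfig(
        countries=[
            CountrySimConfig("KE", n_sires=103, n_dams=1900, n_cows=2333,
                             n_herds=25, year_start=1979, year_end=2014),
            CountrySimConfig("SA", n_sires=505, n_dams=18000, n_cows=25208,
                             n_herds=150, year_start=1997, year_end=2014),
        ],
        n_common_sires=40,
        seed=seed,
        country_mean=dict(DEFAULT_COUNTRY_MEANS),
    )


def desk_scale_config(seed: int = 0, n_common_sires: int = 10,
                      ke_sires: int = 20, ke_cows: int = 300,
                      sa_sires: int = 60, sa_cows: int = 1200) -> SimConfig:
    """A scaled-down study preserving the structure: a small connected Kenyan
    herdbook, a larger South African one, shared sires between them."""
    return SimConfig(
        countries=[
            CountrySimConfig("KE", n_sires=ke_sires, n_dams=max(ke_cows * 3 // 4, 1),
                             n_cows=ke_cows, n_herds=5, year_start=2008, year_end=2013),
            CountrySimConfig("SA", n_sires=sa_sires, n_dams=max(sa_cows * 3 // 4, 1),
                             n_cows=sa_cows, n_herds=12, year_start=2008, year_end=2013),
        ],
        n_common_sires=n_common_sires,
        seed=seed,
        country_mean=dict(DEFAULT_COUNTRY_MEANS),
    )
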