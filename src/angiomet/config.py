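"""Configuration schema, validation and unit resolution.

A :class:`SimConfig` mirrors the YAML layout::

    lattice:   {dims, spacing}
    cells:     {dt, density_cutoff, quiescent_cancer_uptake, normal: {...}, cancer: {...}}
    vasculature: {dx_max, sprout_p_max, ...}
    field:     {glucose: {...}, oxygen: {...}, vegf: {...}}
    metabolism: {enabled, network, rtol, atol}
    run:       {end_time, snapshot_every, burn_in, seed, ...}

Every physical quantity may be written as ``"<value> <unit>"`` (converted to
the internal um/h/mmol/l/Pa system at load time, see :mod:`angiomet.units`)
or as a bare number already in internal units.  Unknown keys are rejected;
all defaults are materialized into the resolved config, which is echoed to
the run manifest.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dfield, fields as dfields, is_dataclass

import yaml

from .errors import ConfigError
from .units import parse_quantity


def _q(kind: str, default):
    """A quantity field: parsed with unit conversion."""
    return dfield(default=default, metadata={"q": kind})


class _Quantified:
    """Parses ``"<value> <unit>"`` quantity defaults/overrides at construction."""

    def __post_init__(self):
        for f in dfields(self):
            v = getattr(self, f.name)
            if "q" in f.metadata and isinstance(v, str):
                setattr(self, f.name, parse_quantity(v, f.metadata["q"], f.name))


# ---------------------------------------------------------------------------
# sections


@dataclass
class LatticeConfig(_Quantified):
    """Cubic simulation lattice; default 64^3 sites at 20 um spacing (1.28 mm side)."""
    dims: tuple = (64, 64, 64)
    spacing: float = _q("length", "20 um")

    def side_lengths(self):
        return tuple(d * self.spacing for d in self.dims)


@dataclass
class CellTypeParams(_Quantified):
    """Subcellular and automaton parameters for one cell type.

    The cycle progresses at an oxygen-Michaelis rate saturating at
    ``1/t_cycle``; p53 follows ``dp/dt = p53_prod - p53_deg*f(ox)*p`` (hypoxia
    suppresses degradation so p53 accumulates) and intracellular VEGF follows
    ``dv/dt = vegf_prod*k_vegf_ox/(k_vegf_ox+ox) - vegf_deg*v`` (hypoxia
    enhances production).
    """
    t_cycle: float = _q("time", "48 h")                 # minimum cycle time
    k_phi_ox: float = _q("concentration", "0.02 mmol/l")  # cycle O2 half-saturation
    p53_prod: float = _q("rate", "0.2 1/h")
    p53_deg: float = _q("rate", "2.0 1/h")
    k_p53_ox: float = _q("concentration", "0.02 mmol/l")
    vegf_prod: float = _q("rate", "0.4 1/h")
    vegf_deg: float = _q("rate", "0.6 1/h")
    k_vegf_ox: float = _q("concentration", "0.02 mmol/l")
    vegf_hill: float = 3.0   # Hill exponent of the hypoxic VEGF switch
    p53_thr_low_density: float = 0.8
    p53_thr_high_density: float = 1.6
    ox_quiesce_enter: float = _q("concentration", "0.035 mmol/l")
    ox_quiesce_leave: float = _q("concentration", "0.045 mmol/l")
    t_quiesce_max: float = _q("time", "24 h")
    movement_rate: float = _q("rate", "0.05 1/h")
    cdh_level: float = 0.0   # passive channels, no dynamics by default
    p27_level: float = 0.0

    def validate(self, path, problems):
        for name in ("t_cycle", "k_phi_ox", "p53_prod", "p53_deg", "k_p53_ox",
                     "vegf_prod", "vegf_deg", "k_vegf_ox", "t_quiesce_max"):
            if getattr(self, name) <= 0:
                problems.append(f"{path}.{name}: must be > 0")
        if self.movement_rate < 0:
            problems.append(f"{path}.movement_rate: must be >= 0")
        if self.ox_quiesce_enter > self.ox_quiesce_leave:
            problems.append(f"{path}: ox_quiesce_enter must be <= ox_quiesce_leave")


def _normal_defaults():
    return CellTypeParams()


def _cancer_defaults():
    return CellTypeParams(
        t_cycle=24.0,
        k_phi_ox=0.01,
        p53_thr_low_density=1e12,   # cancer apoptosis via prolonged quiescence instead
        p53_thr_high_density=1e12,
        ox_quiesce_enter=0.012,
        ox_quiesce_leave=0.025,
        t_quiesce_max=150.0,
    )


@dataclass
class CellsConfig(_Quantified):
    dt: float = _q("time", "0.5 h")
    density_cutoff: float = 0.5   # occupied-neighbour fraction separating low/high density
    quiescent_cancer_uptake: str = "cancer"   # or "normal"
    normal: CellTypeParams = dfield(default_factory=_normal_defaults)
    cancer: CellTypeParams = dfield(default_factory=_cancer_defaults)

    def validate(self, path, problems):
        if self.dt <= 0:
            problems.append(f"{path}.dt: must be > 0")
        if not 0 <= self.density_cutoff <= 1:
            problems.append(f"{path}.density_cutoff: must be in [0,1]")
        if self.quiescent_cancer_uptake not in ("cancer", "normal"):
            problems.append(f"{path}.quiescent_cancer_uptake: must be 'cancer' or 'normal'")
        self.normal.validate(f"{path}.normal", problems)
        self.cancer.validate(f"{path}.cancer", problems)


@dataclass
class VascularConfig(_Quantified):
    """Angiogenesis, anastomosis and blood-flow parameters."""
    dx_max: float = _q("length", "100 um")      # maximum anastomosis distance
    sprout_p_max: float = _q("rate", "0.4 1/h")  # saturating sprouting probability rate
    sprout_v_half: float = 0.02                  # VEGF half-saturation (field units)
    sprout_v_min: float = 0.005                  # VEGF threshold below which no sprouting
    bias_weight: float = 2000.0                  # chemotactic bias (um per field unit)
    tip_speed: float = _q("sites_rate", "1.0 sites/h")
    max_sprout_age: float = _q("time", "60 h")
    tip_exclusion_radius: float = _q("length", "100 um")
    r_init: float = _q("length", "6 um")
    r_min: float = _q("length", "2 um")
    r_max: float = _q("length", "12 um")
    viscosity: float = _q("viscosity", "1.2e-3 Pa*s")
    pressure_in: float = _q("pressure", "4000 Pa")
    pressure_out: float = _q("pressure", "2000 Pa")
    remodel_rate: float = _q("rate", "0.02 1/h")
    shear_ref: float = _q("shear", "15 Pa")
    prune_after: float = _q("time", "40 h")
    flow_threshold_rel: float = 1e-6   # fraction of net inflow defining "functional"
    sor_omega: float = 0.0   # 0 = auto (near-optimal from Jacobi spectral radius)
    flow_tol: float = 1e-14
    flow_max_iter: int = 50000

    def validate(self, path, problems):
        for name in ("dx_max", "r_init", "r_min", "r_max", "viscosity",
                     "shear_ref", "sprout_v_half"):
            if getattr(self, name) <= 0:
                problems.append(f"{path}.{name}: must be > 0")
        if self.r_min > self.r_max:
            problems.append(f"{path}: r_min must be <= r_max")
        if not (self.r_min <= self.r_init <= self.r_max):
            problems.append(f"{path}: r_init must lie in [r_min, r_max]")
        if not 0 <= self.sor_omega < 2:
            problems.append(f"{path}.sor_omega: must be in [0,2) (0 = auto)")
        if self.sprout_p_max < 0 or self.tip_speed < 0:
            problems.append(f"{path}: sprout_p_max and tip_speed must be >= 0")


@dataclass
class UptakeConfig(_Quantified):
    """Michaelis-Menten uptake ``r_max*c/(K_M+c)`` (volumetric, per occupied site)."""
    r_max: float = _q("conc_rate", "0 mmol/(l*h)")
    k_m: float = _q("concentration", "0.2 mmol/l")

    def validate(self, path, problems):
        if self.r_max < 0:
            problems.append(f"{path}.r_max: must be >= 0")
        if self.k_m <= 0:
            problems.append(f"{path}.k_m: must be > 0")


@dataclass
class FieldConfig(_Quantified):
    """One diffusible species: quasi-steady reaction-diffusion parameters."""
    d: float = _q("diffusivity", "2.0e-6 cm^2/s")
    p_wall: float = _q("speed", "2000 um/h")      # vessel-wall permeation coefficient
    c_blood: float = _q("concentration", "5.0 mmol/l")
    decay: float = _q("rate", "0 1/h")
    secretion_rate: float = _q("rate", "0 1/h")   # per-site source per unit intracellular VEGF
    bc: str = "neumann"                           # 'neumann' (zero-flux) or 'dirichlet'
    bc_value: float = _q("concentration", "0 mmol/l")
    uptake_normal: UptakeConfig = dfield(default_factory=UptakeConfig)
    uptake_cancer: UptakeConfig = dfield(default_factory=UptakeConfig)
    tol: float = 1e-8
    max_picard: int = 200

    def validate(self, path, problems):
        if self.d <= 0:
            problems.append(f"{path}.d: must be > 0")
        if self.p_wall < 0 or self.c_blood < 0 or self.decay < 0:
            problems.append(f"{path}: p_wall, c_blood and decay must be >= 0")
        if self.bc not in ("neumann", "dirichlet", "dirichlet_x0"):
            problems.append(f"{path}.bc: must be 'neumann', 'dirichlet' or 'dirichlet_x0'")
        self.uptake_normal.validate(f"{path}.uptake_normal", problems)
        self.uptake_cancer.validate(f"{path}.uptake_cancer", problems)


def _glucose_defaults():
    return FieldConfig(
        uptake_normal=UptakeConfig(r_max=0.66, k_m=0.2),
        uptake_cancer=UptakeConfig(r_max=3.3, k_m=0.2),
    )


def _oxygen_defaults():
    return FieldConfig(
        d=2.0e-5 * 1e8 * 3600.0,   # 2.0e-5 cm^2/s
        p_wall=2.0e5,
        c_blood=0.13,
        uptake_normal=UptakeConfig(r_max=5.0, k_m=0.01),
        uptake_cancer=UptakeConfig(r_max=240.0, k_m=0.01),
    )


def _vegf_defaults():
    return FieldConfig(
        d=1.0e-6 * 1e8 * 3600.0,   # 1.0e-6 cm^2/s
        p_wall=1000.0,             # vessels clear VEGF (c_blood = 0 acts as a sink)
        c_blood=0.0,
        decay=10.0,
        secretion_rate=1.0,
    )


@dataclass
class FieldsConfig(_Quantified):
    glucose: FieldConfig = dfield(default_factory=_glucose_defaults)
    oxygen: FieldConfig = dfield(default_factory=_oxygen_defaults)
    vegf: FieldConfig = dfield(default_factory=_vegf_defaults)

    def validate(self, path, problems):
        for name in ("glucose", "oxygen", "vegf"):
            getattr(self, name).validate(f"{path}.{name}", problems)


@dataclass
class MetabolismConfig(_Quantified):
    enabled: bool = True
    network: str = ""        # path to a network definition; empty -> bundled default
    rtol: float = 1e-5
    atol: float = 1e-8
    # field species feeding the clamped externals of the metabolic network
    env_map: dict = dfield(default_factory=lambda: {"glc_ext": "glucose", "o2_ext": "oxygen"})

    def validate(self, path, problems):
        if self.rtol <= 0 or self.atol <= 0:
            problems.append(f"{path}: rtol and atol must be > 0")


@dataclass
class RunConfig(_Quantified):
    end_time: float = _q("time", "350 h")
    snapshot_every: float = _q("time", "10 h")
    burn_in: float = _q("time", "100 h")
    initial_healthy_fraction: float = 0.3
    tumour_radius_sites: int = 2
    seed: int = 0

    def validate(self, path, problems):
        if self.end_time < 0 or self.burn_in < 0:
            problems.append(f"{path}: end_time and burn_in must be >= 0")
        if self.snapshot_every <= 0:
            problems.append(f"{path}.snapshot_every: must be > 0")
        if not 0 <= self.initial_healthy_fraction <= 1:
            problems.append(f"{path}.initial_healthy_fraction: must be in [0,1]")
        if self.tumour_radius_sites < -1:
            problems.append(f"{path}.tumour_radius_sites: must be >= 0 (-1 disables implantation)")


@dataclass
class SimConfig(_Quantified):
    lattice: LatticeConfig = dfield(default_factory=LatticeConfig)
    cells: CellsConfig = dfield(default_factory=CellsConfig)
    vasculature: VascularConfig = dfield(default_factory=VascularConfig)
    field: FieldsConfig = dfield(default_factory=FieldsConfig)
    metabolism: MetabolismConfig = dfield(default_factory=MetabolismConfig)
    run: RunConfig = dfield(default_factory=RunConfig)

    def validate(self):
        problems: list[str] = []
        if len(self.lattice.dims) != 3 or any(int(d) < 1 for d in self.lattice.dims):
            problems.append("lattice.dims: three integers >= 1 required")
        if self.lattice.spacing <= 0:
            problems.append("lattice.spacing: must be > 0")
        self.cells.validate("cells", problems)
        self.vasculature.validate("vasculature", problems)
        self.field.validate("field", problems)
        self.metabolism.validate("metabolism", problems)
        self.run.validate("run", problems)
        if problems:
            raise ConfigError(problems)
        return self

    def to_dict(self):
        """Resolved config (internal units, all defaults materialized)."""
        return _to_dict(self)


# ---------------------------------------------------------------------------
# resolution machinery


def _to_dict(obj):
    if is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dfields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def _apply(instance, raw: dict, path: str, problems: list):
    """Overlay ``raw`` onto a default dataclass instance, converting units."""
    known = {f.name: f for f in dfields(instance)}
    for key, value in raw.items():
        where = f"{path}.{key}" if path else key
        if key not in known:
            problems.append(f"unknown key '{where}'")
            continue
        f = known[key]
        current = getattr(instance, key)
        if is_dataclass(current):
            if not isinstance(value, dict):
                problems.append(f"{where}: expected a mapping")
                continue
            _apply(current, value, where, problems)
        elif "q" in f.metadata:
            try:
                setattr(instance, key, parse_quantity(value, f.metadata["q"], where))
            except ConfigError as exc:
                problems.extend(exc.problems)
        elif key == "dims":
            try:
                dims = tuple(int(v) for v in value)
            except (TypeError, ValueError):
                problems.append(f"{where}: expected a triple of integers")
                continue
            setattr(instance, key, dims)
        else:
            setattr(instance, key, copy.deepcopy(value))
    return instance


def resolve_config(raw: dict | None) -> SimConfig:
    """Build a validated :class:`SimConfig` from a raw mapping (may be empty)."""
    cfg = SimConfig()
    problems: list[str] = []
    if raw:
        if not isinstance(raw, dict):
            raise ConfigError(["top level of the config must be a mapping"])
        _apply(cfg, raw, "", problems)
    if problems:
        raise ConfigError(problems)
    return cfg.validate()


def load_config(path) -> SimConfig:
    """Load, unit-convert and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return resolve_config(raw or {})


def default_config() -> SimConfig:
    return SimConfig().validate()
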