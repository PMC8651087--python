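"""Simulation configuration: the single source of truth for a run.

All quantities use the model's internal unit system — micrometres (μm),
minutes (min) and piconewtons (pN) — with no conversion at API boundaries.
Dimensionless factors (``k_adh``, the suppression weights ``delta_R_e`` /
``delta_R_l``) are ratios relative to the total propulsive force or to the
clock advance rate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import yaml

__all__ = ["StrainFraction", "SimulationConfig", "WT", "OE", "NR", "STRAIN_NAMES"]

# Strain labels (integer codes used throughout the engine).
WT = 0  #: parent strain — weak adhesion, reversing
OE = 1  #: TraAB overexpressor — strong adhesion among same-allele OE, reversing
NR = 2  #: nonreversing (Frz-mutant-like) — weak adhesion, reversal clock disabled

STRAIN_NAMES = {WT: "WT", OE: "OE", NR: "NR"}
_STRAIN_CODES = {v: k for k, v in STRAIN_NAMES.items()}


@dataclass(frozen=True)
class StrainFraction:
    """One component of the population mix: a strain label, a TraAB allele
    identity, and the fraction of agents carrying both."""

    strain: str
    allele: int
    fraction: float

    def __post_init__(self) -> None:
        if self.strain not in _STRAIN_CODES:
            raise ValueError(f"unknown strain label {self.strain!r}; expected WT/OE/NR")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")

    @property
    def strain_code(self) -> int:
        return _STRAIN_CODES[self.strain]


@dataclass
class SimulationConfig:
    """Parameters of a gliding-rod population simulation.

    Defaults are the reference parameterisation of the model: a 6-μm,
    7-node flexible rod propelled by a 55-pN distributed motor on a
    200 × 200 μm periodic domain at density 0.074 agents/μm².
    """

    # --- agent geometry and mechanics ---
    L: float = 6.0                #: agent length (μm)
    w: float = 0.5                #: agent width (μm)
    m: float = 1.2e-15            #: agent mass (kg); documentary only — dynamics are overdamped
    N: int = 7                    #: nodes per agent
    k_b: float = 10.0             #: angular spring constant (pN·μm/rad)
    F_T: float = 55.0             #: total propulsive force per agent (pN)
    c: float = 22.0               #: agent drag coefficient (pN·min/μm); per node c/N
    k_a: float = 100.0            #: substrate adhesion spring constant (pN/μm)
    d_a_max: float = 0.5          #: substrate anchor break distance (μm)
    k_rep: float = 300.0          #: contact repulsion stiffness (pN/μm); a tunable

    # --- clocks ---
    tau_r: float = 8.0            #: reversal period (min); math.inf disables reversals
    tau_t: float = 5.0            #: random-turn trigger period (min)
    turn_duration: float = 1.0    #: duration of a 90° head-force turn (min)

    # --- domain and integration ---
    L_sim: float = 200.0          #: periodic square domain edge (μm)
    eta: float = 0.074            #: agent density (agents/μm²)
    dt: float = 0.0067            #: integration time step (min)
    max_node_step: float = 0.05   #: per-node displacement cap per step (μm)

    # --- cell-cell adhesion and contact signalling ---
    adhesion_enabled: bool = True
    k_adh_wt: float = 0.01        #: adhesion force factor for any pair not OE–OE
    k_adh_oe: float = 0.1         #: adhesion force factor for same-allele OE–OE pairs
    delta_R_e: float = 1.0        #: end-end reversal suppression factor
    delta_R_l: float = 0.04       #: lateral reversal suppression factor
    tau_thr: float = 5.0          #: minimum bond age before it suppresses (min)
    d_thr_ee: float = 1.5         #: end-end adhesion reach (μm)
    d_thr_lat: float = 0.9        #: lateral adhesion reach (μm)
    suppression_per_agent_pair: bool = False  #: count agent pairs instead of node pairs

    # --- slime field ---
    slime_following_enabled: bool = True
    slime_cell_size: float = 0.5  #: trail grid resolution (μm); one agent width
    omega_s: float = 30.0         #: maximum slime steering rate (deg/min)
    slime_decay_min: float = 20.0  #: trail lifetime (min); math.inf = persistent

    # --- run control ---
    run_duration: float = 250.0   #: simulated time (min)
    snapshot_interval: float = 1.0  #: recording interval (min)
    seed: int = 0
    strain_composition: list[StrainFraction] = field(
        default_factory=lambda: [StrainFraction("WT", 1, 1.0)]
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities ---------------------------------------------
    @property
    def n_agents(self) -> int:
        """Population size M = round(η·L_sim²)."""
        return int(round(self.eta * self.L_sim**2))

    @property
    def segment_length(self) -> float:
        """Fixed spacing between consecutive nodes, L/(N−1)."""
        return self.L / (self.N - 1)

    @property
    def c_node(self) -> float:
        """Per-node drag coefficient: the agent coefficient c split over
        its N nodes."""
        return self.c / self.N

    @property
    def free_speed(self) -> float:
        """Closed-form gliding speed of an isolated straight agent in the
        overdamped limit: total motor force over total drag, F_T/c
        (≈ 2.5 μm/min at defaults)."""
        return self.F_T / self.c

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        positive = {
            "L": self.L, "w": self.w, "N": self.N, "k_b": self.k_b,
            "F_T": self.F_T, "c": self.c, "k_a": self.k_a,
            "d_a_max": self.d_a_max, "k_rep": self.k_rep,
            "tau_r": self.tau_r, "tau_t": self.tau_t,
            "turn_duration": self.turn_duration, "L_sim": self.L_sim,
            "eta": self.eta, "dt": self.dt, "d_thr_ee": self.d_thr_ee,
            "d_thr_lat": self.d_thr_lat, "run_duration": self.run_duration,
            "snapshot_interval": self.snapshot_interval,
            "slime_cell_size": self.slime_cell_size,
            "max_node_step": self.max_node_step,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.N < 3:
            raise ValueError("at least 3 nodes are required for a flexible rod")
        if self.eta * self.L_sim**2 < 1:
            raise ValueError("domain too small: eta*L_sim**2 must be >= 1")
        for name in ("k_adh_wt", "k_adh_oe", "delta_R_e", "delta_R_l", "tau_thr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = sum(s.fraction for s in self.strain_composition)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"strain fractions must sum to 1, got {total}")

    # -- (de)serialisation ----------------------------------------------
    def replace(self, **overrides) -> "SimulationConfig":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strain_composition"] = [
            {"strain": s.strain, "allele": s.allele, "fraction": s.fraction}
            for s in self.strain_composition
        ]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        comp = data.pop("strain_composition", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if comp is not None:
            cfg.strain_composition = [
                s if isinstance(s, StrainFraction) else StrainFraction(**s) for s in comp
            ]
            cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
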