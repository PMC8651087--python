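"""Cell-cell adhesion bonds and the contact-gated reversal clock.

Two bond geometries exist:

* **end-end** — the head node of one agent attached to the tail node of
  another, with reach ``d_thr_ee`` (1.5 μm); the cell envelope stretches
  further along the long axis,
* **lateral** — any other node pair of two distinct agents (flank-flank,
  head-head, tail-tail, flank-end), with reach ``d_thr_lat`` (0.9 μm).

A bond exerts the piecewise-linear force

    F_adh(d) = k_adh · (d − w)/w · F_T      for w < d ≤ d_thr,  else 0,

pulling the two nodes together, where ``k_adh`` is the pair's adhesion
factor (allele-aware, see :func:`pair_adhesion_coefficient`).  A bond older
than ``tau_thr`` feeds the reversal-suppression sums of both partner
agents; the clock of agent i advances as

    r_{t+1} = max[r_t + dt·(1 − Σ_ee δR_e − Σ_lat δR_l), 0]   if r_t < τ_r
    r_{t+1} = 0  (and a reversal fires)                        if r_t ≥ τ_r

so a single sustained end-end contact (δR_e = 1) freezes the clock while
lateral contacts (δR_l = 0.04) each slow it by 4%; enough of them rewind it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NR, OE, SimulationConfig, STRAIN_NAMES, _STRAIN_CODES

__all__ = [
    "AdhesionBond",
    "END_END",
    "LATERAL",
    "pair_adhesion_coefficient",
    "adhesion_force",
    "update_bonds",
    "reversal_clock_update",
]

END_END = 0
LATERAL = 1


@dataclass
class AdhesionBond:
    """A node-pair attachment between two agents."""

    agent_a: int
    agent_b: int
    node_a: int
    node_b: int
    bond_type: int            # END_END or LATERAL
    formed_at: float          # min
    current_distance: float   # μm

    def age(self, now: float) -> float:
        return now - self.formed_at


def _strain_code(strain) -> int:
    if isinstance(strain, str):
        try:
            return _STRAIN_CODES[strain]
        except KeyError:
            raise ValueError(f"unknown strain label {strain!r}") from None
    if strain not in STRAIN_NAMES:
        raise ValueError(f"unknown strain code {strain!r}")
    return int(strain)


def pair_adhesion_coefficient(
    strain_a, allele_a: int, strain_b, allele_b: int, cfg: SimulationConfig
) -> float:
    """Adhesion force factor k_adh for a pair of agents (symmetric).

    Mismatched TraAB alleles cannot adhere (k_adh = 0); two same-allele
    overexpressors adhere 10× more strongly (``k_adh_oe``) than every other
    compatible pair (``k_adh_wt``).
    """
    a, b = _strain_code(strain_a), _strain_code(strain_b)
    if not cfg.adhesion_enabled:
        return 0.0
    if allele_a != allele_b:
        return 0.0
    if a == OE and b == OE:
        return cfg.k_adh_oe
    return cfg.k_adh_wt


def adhesion_force(d: float, k_adh: float, cfg: SimulationConfig, bond_type: int) -> float:
    """Magnitude of the adhesion force at node separation ``d`` (μm).

    Zero outside the bond's reach and at or below contact (d ≤ w); linear
    in the stretch (d − w)/w otherwise, scaled by k_adh·F_T.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    d_thr = cfg.d_thr_ee if bond_type == END_END else cfg.d_thr_lat
    if d > d_thr or d <= cfg.w:
        return 0.0
    return k_adh * (d - cfg.w) / cfg.w * cfg.F_T


def update_bonds(agents, t: float, bonds: list[AdhesionBond], cfg: SimulationConfig,
                 box: float | None = None) -> list[AdhesionBond]:
    """Advance the bond set one step for a small population of agents.

    New end-end bonds form when a head node and a foreign tail node come
    within ``d_thr_ee`` (and the pair adheres at all); any other foreign
    node pair within ``d_thr_lat`` forms a lateral bond.  A bond breaks as
    soon as its distance exceeds its reach; a re-formed bond starts at age
    zero.  Reference implementation (quadratic in nodes) used by tests and
    small fixtures; the engine runs an equivalent jitted version.
    """
    box = cfg.L_sim if box is None else box
    existing = {
        (b.agent_a, b.node_a, b.agent_b, b.node_b): b for b in bonds
    }
    out: list[AdhesionBond] = []
    for ia in range(len(agents)):
        for ib in range(ia + 1, len(agents)):
            A, B = agents[ia], agents[ib]
            k = pair_adhesion_coefficient(
                A.strain_label, A.allele_id, B.strain_label, B.allele_id, cfg
            )
            if k == 0.0:
                continue
            for na in range(A.n_nodes):
                for nb in range(B.n_nodes):
                    delta = B.node_positions[nb] - A.node_positions[na]
                    delta -= box * np.round(delta / box) if np.isfinite(box) else 0.0
                    d = float(np.hypot(*delta))
                    ee = (na == A.head_index and nb == B.tail_index) or (
                        na == A.tail_index and nb == B.head_index
                    )
                    btype = END_END if ee else LATERAL
                    reach = cfg.d_thr_ee if ee else cfg.d_thr_lat
                    if d > reach:
                        continue
                    key = (A.agent_id, na, B.agent_id, nb)
                    prev = existing.get(key)
                    if prev is not None and prev.bond_type == btype:
                        prev.current_distance = d
                        out.append(prev)
                    else:
                        out.append(
                            AdhesionBond(A.agent_id, B.agent_id, na, nb, btype, t, d)
                        )
    return out


def reversal_clock_update(
    r_t: float,
    n_ee_active: int,
    n_lat_active: int,
    dt: float,
    cfg: SimulationConfig,
    strain="WT",
) -> tuple[float, bool]:
    """One step of the reversal clock; returns (r_{t+1}, reversal_fired).

    ``n_ee_active`` / ``n_lat_active`` count only bonds older than
    ``tau_thr``.  Nonreversing agents hold their clock at zero and never
    fire.  A clock at or past τ_r fires and resets.
    """
    if n_ee_active < 0 or n_lat_active < 0:
        raise ValueError("active bond counts must be non-negative")
    if _strain_code(strain) == NR:
        return 0.0, False
    if r_t >= cfg.tau_r:
        return 0.0, True
    rate = 1.0 - n_ee_active * cfg.delta_R_e - n_lat_active * cfg.delta_R_l
    return max(r_t + dt * rate, 0.0), False
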