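"""Canned computational experiments: the phenotype matrix over strain and
mechanism ablations, the reversal-period sweep, and the adhesion-strength
sweep.

Each condition is a named manifest — a base configuration plus overrides
and an expected qualitative phenotype (circular aggregates present, absent,
or present with both sub-populations intermixed).  The phenotype verdict is
the aggregate detector's call on the final snapshot, decided per condition
by majority over seeds.  The ``reduced`` scale shrinks the domain edge to
100 μm (density preserved, so M scales with area) to keep desk runtimes
reasonable; ``full`` is the 200-μm reference domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import detect_aggregates, suppression_stats
from .config import SimulationConfig, StrainFraction
from .engine import run as run_sim

__all__ = [
    "ExperimentManifest",
    "standard_manifests",
    "phenotype_verdict",
    "phenotype_matrix",
    "reversal_period_sweep",
    "adhesion_sweep",
]

SCALES = {"full": 200.0, "reduced": 100.0}

#: CA with both sub-populations represented at ≥ this fraction counts as mixed
MIXED_MINORITY_FRACTION = 0.2


@dataclass
class ExperimentManifest:
    """One named condition of the phenotype matrix."""

    name: str
    overrides: dict = field(default_factory=dict)
    composition: list[StrainFraction] | None = None
    expected: str = "no_CA"   # "CA" | "no_CA" | "mixed_CA"
    description: str = ""

    def build_config(self, scale="reduced", run_duration: float = 250.0,
                     **extra) -> SimulationConfig:
        L_sim = SCALES.get(scale, None)
        if L_sim is None:
            L_sim = float(scale)
        cfg = SimulationConfig(L_sim=L_sim, run_duration=run_duration)
        merged = dict(self.overrides)
        merged.update(extra)
        for key, value in merged.items():
            if not hasattr(cfg, key):
                raise ValueError(f"{self.name}: unknown config key {key!r}")
            setattr(cfg, key, value)
        if self.composition is not None:
            cfg.strain_composition = list(self.composition)
        cfg.validate()
        return cfg


def standard_manifests() -> dict[str, ExperimentManifest]:
    """The ten phenotype-matrix conditions.

    Naming: strain ablations over (reversals, adhesion, contact signalling,
    slime following) for single populations, then the three 1:1 mixtures.
    """
    wt = [StrainFraction("WT", 1, 1.0)]
    oe = [StrainFraction("OE", 1, 1.0)]
    nr = [StrainFraction("NR", 1, 1.0)]
    no_suppression = {"delta_R_e": 0.0, "delta_R_l": 0.0}
    m = [
        ExperimentManifest(
            "reversing_adhesion", {**no_suppression}, wt, "no_CA",
            "reversing agents with weak adhesion, no contact signalling: "
            "streams, no CAs",
        ),
        ExperimentManifest(
            "nonreversing_no_adhesion", {"adhesion_enabled": False}, nr, "CA",
            "nonreversing agents without adhesion form CAs",
        ),
        ExperimentManifest(
            "nonreversing_adhesion", {}, nr, "CA",
            "nonreversing agents with adhesion form CAs",
        ),
        ExperimentManifest(
            "nonreversing_no_slime",
            {"adhesion_enabled": False, "slime_following_enabled": False}, nr, "no_CA",
            "nonreversing agents without slime following do not form CAs",
        ),
        ExperimentManifest(
            "wt_contact_signalling", {}, wt, "no_CA",
            "weakly adhesive reversing agents with the 5-min signalling gate: "
            "a minority suppressed, no CAs",
        ),
        ExperimentManifest(
            "oe_contact_signalling", {}, oe, "CA",
            "strongly adhesive reversing agents: prevalent suppression and CAs",
        ),
        ExperimentManifest(
            "wt_no_time_threshold", {"tau_thr": 0.0}, wt, "CA",
            "removing the bond-age gate lets even weak adhesion suppress "
            "reversals and form CAs",
        ),
        ExperimentManifest(
            "mix_oe_incompatible_alleles", {},
            [StrainFraction("OE", 1, 0.5), StrainFraction("OE", 2, 0.5)], "mixed_CA",
            "two OE populations with incompatible TraAB alleles: CAs form "
            "with both labels intermixed",
        ),
        ExperimentManifest(
            "mix_oe_wt", {},
            [StrainFraction("OE", 1, 0.5), StrainFraction("WT", 1, 0.5)], "no_CA",
            "WT agents break up OE contacts: no CAs in the 1:1 mixture",
        ),
        ExperimentManifest(
            "mix_oe_nr", {},
            [StrainFraction("OE", 1, 0.5), StrainFraction("NR", 1, 0.5)], "mixed_CA",
            "OE mixed with weakly adhesive nonreversing agents: mixed CAs",
        ),
    ]
    return {man.name: man for man in m}


def _largest_ca(reports):
    cas = [r for r in reports if r.is_circular_aggregate]
    return max(cas, key=lambda r: len(r.members)) if cas else None


#: late-run scoring window (min), sampling stride (min), and the fraction
#: of sampled snapshots that must show a CA for a positive verdict.  At
#: reduced domain scale a CA's rotational order fluctuates around the
#: threshold (few tens of members), so presence is scored over a window
#: rather than the single final frame; sustained rotation clears the
#: fraction easily while momentary collision swirls do not.
VERDICT_WINDOW_MIN = 100.0
VERDICT_STRIDE_MIN = 5.0
CA_PRESENCE_FRACTION = 0.25


def _window_indices(traj, window_min=VERDICT_WINDOW_MIN,
                    stride_min=VERDICT_STRIDE_MIN):
    times = np.asarray(traj.times)
    t_end = times[-1]
    lo = max(t_end - window_min, times[0])
    wanted = np.arange(lo, t_end + 1e-9, stride_min)
    return sorted({int(np.argmin(np.abs(times - t))) for t in wanted})


def _is_mixed(traj, ca) -> bool:
    key = traj.strain[ca.members] * 1000 + traj.allele[ca.members]
    counts = pd.Series(key).value_counts(normalize=True)
    return len(counts) >= 2 and counts.iloc[1] >= MIXED_MINORITY_FRACTION


def phenotype_verdict(traj, manifest: ExperimentManifest | None = None,
                      window_min: float = VERDICT_WINDOW_MIN,
                      stride_min: float = VERDICT_STRIDE_MIN,
                      presence_fraction: float = CA_PRESENCE_FRACTION,
                      **detector_kwargs) -> dict:
    """Score one run: CA presence over the late window, size, suppression,
    and label mixing.

    A run "forms CAs" when the detector finds at least one circular
    aggregate in at least ``presence_fraction`` of the snapshots sampled
    every ``stride_min`` minutes over the final ``window_min`` minutes.
    Size/radius/mixing are reported for the best (highest-order) CA seen
    in the window; the suppressed fraction is the final snapshot's.
    """
    samples = _window_indices(traj, window_min, stride_min)
    hits = 0
    best = None
    best_traj_idx = None
    for s in samples:
        reports = detect_aggregates(traj, time_index=s, **detector_kwargs)
        ca = _largest_ca(reports)
        if ca is not None:
            hits += 1
            if best is None or ca.rotational_order > best.rotational_order:
                best, best_traj_idx = ca, s
    has_ca = hits >= max(1, int(math.ceil(presence_fraction * len(samples))))
    out = {
        "n_samples": len(samples),
        "ca_hits": hits,
        "has_ca": has_ca,
        "largest_ca_size": len(best.members) if best else 0,
        "largest_ca_radius": best.radius if best else math.nan,
        "largest_ca_order": best.rotational_order if best else math.nan,
        "mixed": bool(best is not None and has_ca and _is_mixed(traj, best)),
    }
    frac, life = suppression_stats(traj)
    out["suppressed_fraction"] = frac
    out["mean_bond_lifetime"] = life
    return out


def _verdict_matches(expected: str, scored: dict) -> bool:
    if expected == "CA":
        return scored["has_ca"]
    if expected == "no_CA":
        return not scored["has_ca"]
    if expected == "mixed_CA":
        return scored["has_ca"] and scored["mixed"]
    raise ValueError(f"unknown expected phenotype {expected!r}")


def phenotype_matrix(
    manifests: dict[str, ExperimentManifest] | None = None,
    seeds=(0, 1, 2),
    scale="reduced",
    run_duration: float = 250.0,
    progress: bool = False,
    **detector_kwargs,
) -> pd.DataFrame:
    """Run every condition × seed and tabulate verdicts.

    The per-condition verdict (column ``condition_pass``) requires the
    expected phenotype in a majority of seeds.  A run that aborts is
    recorded as a failed condition, not raised.
    """
    manifests = standard_manifests() if manifests is None else manifests
    rows = []
    for name, man in manifests.items():
        cond_scale = scale.get(name) if isinstance(scale, dict) else scale
        cond_dur = (run_duration.get(name, 250.0)
                    if isinstance(run_duration, dict) else run_duration)
        for seed in seeds:
            row = {"condition": name, "seed": seed, "expected": man.expected}
            try:
                cfg = man.build_config(scale=cond_scale, run_duration=cond_dur)
                traj = run_sim(cfg, seed=seed, progress=progress)
                scored = phenotype_verdict(traj, man, **detector_kwargs)
                row.update(scored)
                row["match"] = _verdict_matches(man.expected, scored)
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - failed condition, not a crash
                row.update({"has_ca": False, "match": False, "error": str(exc)})
            rows.append(row)
    df = pd.DataFrame(rows)
    passed = df.groupby("condition")["match"].agg(
        lambda s: s.sum() > len(s) / 2
    )
    df["condition_pass"] = df["condition"].map(passed)
    return df


def reversal_period_sweep(
    periods=(8.0, 20.0, 40.0, 70.0, 100.0),
    seeds=(0, 1, 2),
    scale="reduced",
    run_duration: float = 250.0,
    include_nonreversing: bool = False,
    progress: bool = False,
    **detector_kwargs,
):
    """Sweep the reversal period for non-adhesive, slime-following agents.

    Returns (onset_period, table): the onset is the smallest grid period
    whose runs form at least one CA in a majority of seeds (None when no
    grid point does).  ``include_nonreversing`` appends a τ_r = ∞ point
    (nonreversing agents).
    """
    grid: list[float] = list(periods)
    if include_nonreversing:
        grid.append(math.inf)
    rows = []
    for tau_r in grid:
        for seed in seeds:
            L_sim = SCALES.get(scale, scale)
            cfg = SimulationConfig(
                L_sim=float(L_sim), run_duration=run_duration, tau_r=tau_r,
                adhesion_enabled=False,
            )
            traj = run_sim(cfg, seed=seed, progress=progress)
            scored = phenotype_verdict(traj, **detector_kwargs)
            rows.append({"tau_r": tau_r, "seed": seed,
                         "ca_hits": scored["ca_hits"],
                         "has_ca": scored["has_ca"]})
    df = pd.DataFrame(rows)
    majority = df.groupby("tau_r")["has_ca"].agg(lambda s: s.sum() > len(s) / 2)
    onset = None
    for tau_r in sorted(majority.index):
        if majority[tau_r] and math.isfinite(tau_r):
            onset = tau_r
            break
    if onset is None and include_nonreversing and majority.get(math.inf, False):
        onset = math.inf
    return onset, df


def adhesion_sweep(
    k_values=(0.0, 0.01, 0.02, 0.04, 0.06, 0.08, 0.1),
    seeds=(0, 1, 2),
    scale="reduced",
    run_duration: float = 250.0,
    progress: bool = False,
) -> pd.DataFrame:
    """Suppressed fraction and mean bond lifetime versus adhesion strength.

    A single reversing population whose self-adhesion factor is swept from
    zero through WT (0.01) to OE (0.1) levels; contact signalling gated at
    the default τ_thr.
    """
    rows = []
    for k in k_values:
        for seed in seeds:
            L_sim = SCALES.get(scale, scale)
            cfg = SimulationConfig(
                L_sim=float(L_sim), run_duration=run_duration,
                k_adh_oe=k, adhesion_enabled=k > 0,
                strain_composition=[StrainFraction("OE", 1, 1.0)],
            )
            traj = run_sim(cfg, seed=seed, progress=progress)
            frac, life = suppression_stats(traj)
            reports = detect_aggregates(traj)
            rows.append({
                "k_adh": k, "seed": seed, "suppressed_fraction": frac,
                "mean_bond_lifetime": life,
                "n_ca": sum(r.is_circular_aggregate for r in reports),
            })
    return pd.DataFrame(rows)
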