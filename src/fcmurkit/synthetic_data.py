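"""Synthetic fixtures for the whole pipeline.

Three generators, each a pure function of its parameters and seed:

* :func:`gen_heating_trajectory` — a Cα model with a programmed two-state
  thermal transition: below ``t_melt`` frames fluctuate about a folded
  jittered-helix reference; above it the model expands progressively so the
  native-contact fraction decays through 0.8 and the radius of gyration
  grows past 14 Å.  Stands in for µs-scale MD heating runs.
* :func:`gen_pentamer_complex` — a C5-symmetric disc of five two-chain
  subunits with a receptor domain docked on each chain of the source
  subunit.  ``good_pose`` mode satisfies the full docking constraint set
  (required/forbidden interface residues, Cµ4 dominance, glycan clearance,
  outward C-termini); the other modes each break their labelled property.
  The real IgM-Fc disc is asymmetric; the fixture is exactly symmetric so
  tiling consistency and the ten-site count are exactly checkable.
* :func:`gen_flow_panel` — replicate MFI records (and optionally log-normal
  event tables) for a mutant panel with programmed index multipliers
  relative to wild type.

Every generator also emits a ground-truth record sufficient to re-derive
the expected downstream quantities without rerunning it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .complex_geometry import DockConstraints, Structure
from .melt_analysis import HeatingTrajectory, TemperatureSchedule

# ---------------------------------------------------------------------------
# heating trajectories


@dataclass(frozen=True)
class MeltSimParams:
    """Conditions for a synthetic heating run.

    The defaults emulate the study's heating protocol: the standard
    two-segment ramp (0.15 K to 400.15 K over 204 ns) sampled with 2000
    frames, a compact Cα folded reference whose Rg sits safely below the
    14 Å unfolding threshold, and a fractional post-melt expansion of
    0.04 per kelvin so both order parameters cross their thresholds within
    a few kelvin of ``t_melt`` (the transition is sharp on the scale of one
    smoothing window, which is what makes it two-state-like).
    """

    t_melt: float                     # K; programmed transition temperature
    seed: int
    n_residues: int = 28
    helix_rise: float = 1.5           # Å per residue
    helix_twist_deg: float = 100.0
    helix_radius: float = 2.3         # Å
    jitter_sd: float = 0.8            # Å; frozen into the folded reference
    pre_noise_sd: float = 0.3         # Å; per-frame thermal fluctuation
    expansion_rate: float = 0.04      # fractional expansion per K above t_melt
    post_noise_rate: float = 0.01     # Å extra noise SD per K above t_melt
    n_frames: int = 2000
    schedule: TemperatureSchedule = field(
        default_factory=TemperatureSchedule.standard_heating
    )

    def __post_init__(self) -> None:
        lo = min(s.T_start for s in self.schedule.segments)
        hi = max(s.T_end for s in self.schedule.segments)
        if not lo <= self.t_melt <= hi:
            raise ValueError(
                f"t_melt {self.t_melt} K outside schedule range [{lo}, {hi}] K"
            )
        if self.pre_noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def helix_reference(params: MeltSimParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered Cα helix centred at the origin — the folded reference."""
    i = np.arange(params.n_residues)
    theta = np.deg2rad(params.helix_twist_deg) * i
    coords = np.stack(
        [
            params.helix_radius * np.cos(theta),
            params.helix_radius * np.sin(theta),
            params.helix_rise * i,
        ],
        axis=1,
    )
    coords += rng.normal(0.0, params.jitter_sd, coords.shape)
    return coords - coords.mean(axis=0)


def gen_heating_trajectory(
    params: MeltSimParams,
) -> tuple[HeatingTrajectory, dict]:
    """Generate a two-state heating trajectory plus its ground truth."""
    rng = np.random.default_rng(params.seed)
    ref = helix_reference(params, rng)
    times = np.linspace(0.0, params.schedule.t_end, params.n_frames)
    temps = params.schedule.temperature(times)
    frames = np.empty((params.n_frames, params.n_residues, 3))
    for k, T in enumerate(temps):
        if T < params.t_melt:
            sd = params.pre_noise_sd
            frames[k] = ref + rng.normal(0.0, sd, ref.shape)
        else:
            dT = T - params.t_melt
            scale = 1.0 + params.expansion_rate * dT
            sd = params.pre_noise_sd + params.post_noise_rate * dT
            frames[k] = ref * scale + rng.normal(0.0, sd, ref.shape)
    traj = HeatingTrajectory(
        coords=frames,
        frame_times=times,
        residue_index=np.arange(params.n_residues),
        schedule=params.schedule,
    )
    truth = {
        "t_melt": params.t_melt,
        "seed": params.seed,
        "n_frames": params.n_frames,
        "n_residues": params.n_residues,
        "expansion_rate": params.expansion_rate,
        "pre_noise_sd": params.pre_noise_sd,
        "folded_rg": float(np.sqrt(((ref - ref.mean(0)) ** 2).sum(1).mean())),
    }
    return traj, truth


def write_trajectory_pdb(traj: HeatingTrajectory, path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL records)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.full(n, "A")
    arr.res_id = traj.residue_index + 1
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    stack = struc.from_template(arr, traj.coords.astype(np.float32))
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# pentamer complexes

MODES = ("good_pose", "clashing", "buried_cterm", "constraint_violating")


@dataclass(frozen=True)
class PentamerParams:
    """Geometry of the toy pentameric disc and the receptor placement mode."""

    seed: int = 0
    n_subunits: int = 5
    residues_per_chain: int = 24      # even, >= 20; first half Cµ3, second Cµ4
    ring_radius: float = 40.0         # Å from disc axis to subunit origin
    receptor_n_residues: int = 12     # >= 12; extras are inert filler
    mode: str = "good_pose"

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("need at least one subunit")
        if self.residues_per_chain < 20 or self.residues_per_chain % 2:
            raise ValueError("residues_per_chain must be even and >= 20")
        if self.receptor_n_residues < 12:
            raise ValueError("receptor needs >= 12 residues")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PentamerFixture:
    pentamer: Structure
    receptors: tuple[Structure, ...]     # the docked pair on the source subunit
    constraints: DockConstraints
    receptor_chains: tuple[str, ...]
    ligand_chains: tuple[str, ...]       # chains of the source subunit
    subunit_chain_pairs: tuple[tuple[str, str], ...]
    regions: dict
    ground_truth: dict

    def complex(self) -> Structure:
        """Pentamer plus the docked receptor pair as one structure."""
        return Structure.concat([self.pentamer, *self.receptors])


def _ca_structure(chain: str, coords: np.ndarray, res_start: int = 1) -> Structure:
    n = coords.shape[0]
    return Structure(
        chain_id=np.full(n, chain),
        res_id=np.arange(res_start, res_start + n),
        res_name=np.full(n, "ALA"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        coords=coords,
    )


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

#: proper rotation flipping the upper half-space onto the lower (C2 about x)
_FLIP_X = np.diag([1.0, -1.0, -1.0])


def _ligand_chain_coords(n: int) -> np.ndarray:
    """One Fc chain as a radial Cα spoke at z = +2: Cµ3 (first half) inward,
    Cµ4 (second half) outward, 1.5 Å grid with the Cµ3/Cµ4 boundary at x=3."""
    half = n // 2
    xs = np.array(
        [3.0 - 1.5 * (half - i) for i in range(half)]
        + [3.0 + 1.5 * j for j in range(n - half)]
    )
    coords = np.zeros((n, 3))
    coords[:, 0] = xs
    coords[:, 2] = 2.0
    return coords


def _receptor_coords(n: int) -> np.ndarray:
    """Receptor domain above the Cµ4 grid (upper chain, subunit frame).

    Residues 3/5/7 are the required interface analogs (CDR2/DE-loop/CDR3),
    sitting 4 Å above ligand Cα positions; residue 2 is an arm adding a few
    Cµ3-boundary contacts so the Cµ4 fraction is high but not trivially 1;
    residues 9-11 are the forbidden CDR1/Y-analogs on the far face; residue
    12 is the outward-pointing C-terminus.  Extra residues are inert filler.
    """
    base = np.array([
        [9.0, 0.0, 6.1],      # 1  body, binding face
        [1.8, 0.0, 5.0],      # 2  arm at the Cµ3/Cµ4 boundary
        [10.5, 0.0, 6.1],     # 3  required (CDR2 analog)
        [11.2, 1.5, 7.0],     # 4  body
        [12.0, 0.0, 6.1],     # 5  required (DE-loop analog, over Q510 analog)
        [12.8, -1.5, 7.0],    # 6  body
        [13.5, 0.0, 6.1],     # 7  required (CDR3 analog)
        [12.0, 0.0, 8.5],     # 8  core
        [10.5, 1.5, 10.0],    # 9  forbidden (CDR1 analog)
        [12.0, 1.5, 10.0],    # 10 forbidden (CDR1 analog)
        [13.5, 1.5, 10.0],    # 11 forbidden (free-face Y analog)
        [12.0, 0.0, 12.0],    # 12 C-terminus
    ])
    extra = []
    for k in range(n - 12):
        ang = 2 * math.pi * k / max(n - 12, 1)
        extra.append([12.0 + 2.2 * math.cos(ang),
                      2.2 * math.sin(ang),
                      9.0 + 0.3 * (k % 2)])
    coords = np.vstack([base] + ([np.array(extra)] if extra else []))
    # keep the C-terminal residue last (highest residue number)
    if extra:
        order = list(range(12 - 1)) + list(range(12, n)) + [11]
        coords = coords[order]
    return coords


def gen_pentamer_complex(params: PentamerParams) -> PentamerFixture:
    """Build the pentameric disc plus a docked receptor pair on subunit 0."""
    import string

    n_res = params.residues_per_chain
    half = n_res // 2
    lig_local = _ligand_chain_coords(n_res)
    rec_local = _receptor_coords(params.receptor_n_residues)

    if params.mode == "clashing":
        rec_local = rec_local + np.array([0.0, 0.0, -3.0])
    elif params.mode == "constraint_violating":
        c = rec_local.mean(axis=0)
        rec_local = (rec_local - c) @ _FLIP_X.T + c
    elif params.mode == "buried_cterm":
        rec_local = rec_local.copy()
        cterm = np.argmax(np.abs(rec_local[:, 2] - 12.0) < 1e-9)
        rec_local[cterm] = [12.0, 0.0, 4.6]

    chain_letters = string.ascii_uppercase
    subunit_pairs: list[tuple[str, str]] = [
        (chain_letters[2 * k], chain_letters[2 * k + 1])
        for k in range(params.n_subunits)
    ]
    shift = np.array([params.ring_radius, 0.0, 0.0])
    parts: list[Structure] = []
    for k, (up, lo) in enumerate(subunit_pairs):
        R = _rot_z(2 * math.pi * k / max(params.n_subunits, 1))
        upper = (lig_local + shift) @ R.T
        lower = (lig_local @ _FLIP_X.T + shift) @ R.T
        parts.append(_ca_structure(up, upper))
        parts.append(_ca_structure(lo, lower))
    pentamer = Structure.concat(parts)

    rec_upper = _ca_structure("R", rec_local + shift)
    rec_lower = _ca_structure("S", rec_local @ _FLIP_X.T + shift)
    receptors = (rec_upper, rec_lower)

    up0, lo0 = subunit_pairs[0]
    excluded: tuple[str, ...] = ()
    if params.n_subunits >= 3:
        excluded = subunit_pairs[1] + subunit_pairs[-1]
    elif params.n_subunits == 2:
        excluded = subunit_pairs[1]
    q_analog = half + 7
    glyco_analog = max(1, half - 8)
    e398_analog = half
    regions = {
        "Cmu3": [(up0, 1, half), (lo0, 1, half)],
        "Cmu4": [(up0, half + 1, n_res), (lo0, half + 1, n_res)],
    }
    constraints = DockConstraints(
        required_receptor=(("R", 3), ("R", 5), ("R", 7)),
        required_ligand=((up0, q_analog),),
        forbidden_receptor=(("R", 9), ("R", 10), ("R", 11)),
        excluded_chains=excluded,
        domain_regions=regions,
        dominant_region="Cmu4",
        min_fraction_dominant=0.75,
        glyco_site=(up0, glyco_analog),
    )
    truth = {
        "mode": params.mode,
        "n_subunits": params.n_subunits,
        # per-aspect expectations: the interface-constraint verdict, the
        # steric clash filter, and C-terminus accessibility are independent
        "expected_constraints_pass": params.mode
        in ("good_pose", "clashing", "buried_cterm"),
        "expected_clash": params.mode in ("clashing", "constraint_violating"),
        "expected_cterm_accessible": params.mode == "good_pose",
        "expected_placements": 2 * params.n_subunits,
        "q510_analog": [up0, q_analog],
        "e398_analog": [up0, e398_analog],
        "glycan_analog": [up0, glyco_analog],
        "seed": params.seed,
    }
    return PentamerFixture(
        pentamer=pentamer,
        receptors=receptors,
        constraints=constraints,
        receptor_chains=("R", "S"),
        ligand_chains=(up0, lo0),
        subunit_chain_pairs=tuple(subunit_pairs),
        regions=regions,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# flow-cytometry panels

#: Programmed index multipliers relative to wild type; directions mirror the
#: mutant panel (loss of binding for the CDR2 deletion, DE-loop swap, CDR3
#: and A-strand mutants; gain for the CDR1 swaps; mouse WT near background).
DEFAULT_CONSTRUCTS = {
    "huWT": 1.0,
    "24-27": 0.3,
    "E41Q": 1.5,
    "M42L": 1.2,
    "41-42": 2.0,
    "N66-": 0.2,
    "79-83": 0.2,
    "Y81C": 1.0,
    "N109K": 0.3,
    "moWT": 0.1,
}


@dataclass(frozen=True)
class PanelParams:
    """Design of a synthetic transductant panel.

    Defaults emulate the staining experiments: three independent replicates
    per construct, ~10 % between-replicate CV on the index, a wild-type
    baseline index of 2.0 and well-separated GFP populations.
    """

    seed: int
    constructs: dict = field(default_factory=lambda: dict(DEFAULT_CONSTRUCTS))
    n_replicates: int = 3
    cv: float = 0.10
    baseline_index: float = 2.0
    probe: str = "IgM"
    gfp_transductant: float = 1100.0
    gfp_control: float = 100.0
    pe_control: float = 100.0
    n_events: int = 2000
    log_sigma: float = 0.5            # log-normal shape of event distributions

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.constructs.values()):
            raise ValueError("index multipliers must be > 0")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")


def gen_flow_panel(
    params: PanelParams, events: bool = False
) -> tuple[pd.DataFrame, dict[tuple[str, int], pd.DataFrame] | None, dict]:
    """Generate replicate MFI records (and optional event tables).

    Replicate indices are ``baseline × multiplier × noise`` with log-normal
    noise of unit mean and coefficient of variation ``cv`` (exact at cv=0),
    so the expected index of every construct is its programmed multiple of
    the wild-type baseline.  Event tables draw log-normal events whose
    arithmetic means equal the per-channel MFIs.
    """
    rng = np.random.default_rng(params.seed)
    sigma = math.sqrt(math.log(1.0 + params.cv**2))
    rows = []
    event_tables: dict[tuple[str, int], pd.DataFrame] = {}
    for construct, mult in params.constructs.items():
        for rep in range(1, params.n_replicates + 1):
            noise = (
                1.0 if params.cv == 0
                else float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
            )
            index = params.baseline_index * mult * noise
            gfp_diff = params.gfp_transductant - params.gfp_control
            pe_t = params.pe_control + index * gfp_diff
            rows.append({
                "construct": construct, "probe": params.probe, "replicate": rep,
                "PE_t": pe_t, "PE_c": params.pe_control,
                "GFP_t": params.gfp_transductant, "GFP_c": params.gfp_control,
                "true_index": index,
            })
            if events:
                event_tables[(construct, rep)] = _lognormal_events(
                    rng, params.n_events, params.log_sigma,
                    pe_t=pe_t, pe_c=params.pe_control,
                    gfp_t=params.gfp_transductant, gfp_c=params.gfp_control,
                )
    records = pd.DataFrame(rows)
    truth = {
        "baseline_index": params.baseline_index,
        "expected_index": {
            c: params.baseline_index * m for c, m in params.constructs.items()
        },
        "cv": params.cv,
        "n_replicates": params.n_replicates,
        "seed": params.seed,
    }
    return records, (event_tables if events else None), truth


def _lognormal_events(
    rng: np.random.Generator, n: int, sigma: float,
    pe_t: float, pe_c: float, gfp_t: float, gfp_c: float,
) -> pd.DataFrame:
    """Event table whose population arithmetic means equal the target MFIs
    (log-normal mean exp(µ + σ²/2) inverted for µ)."""

    def draw(mean: float) -> np.ndarray:
        mu = math.log(mean) - sigma**2 / 2
        return rng.lognormal(mu, sigma, n)

    return pd.DataFrame({
        "PE": np.concatenate([draw(pe_t), draw(pe_c)]),
        "GFP": np.concatenate([draw(gfp_t), draw(gfp_c)]),
        "population": ["transductant"] * n + ["control"] * n,
    })
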