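"""Melting-temperature estimation from heating trajectories.

A heating run ramps the thermostat temperature linearly (fast ramp to 200.15 K
in 4 ns, then slow ramp to 400.15 K over 200 ns, then hold) while frames are
recorded.  Two order parameters track unfolding:

* ``Q`` — the fraction of native contacts retained per frame.  The melting
  temperature is where a centred moving mean of Q first falls below 0.8.
* ``Rg`` — the radius of gyration.  The melting temperature is where its
  moving mean first exceeds 14 Å.

Per-construct repeats are aggregated as sample mean and SD (n-1), with
repeats that never cross reported as censored, and groups are compared with
a pooled-variance two-sided Student's t test (summary-statistic entry point
included so published mean/SD/n rows can be tested directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats

CELSIUS_OFFSET = 273.15


def c_to_k(celsius: float) -> float:
    return celsius + CELSIUS_OFFSET


def k_to_c(kelvin: float) -> float:
    return kelvin - CELSIUS_OFFSET


# ---------------------------------------------------------------------------
# temperature schedule


@dataclass(frozen=True)
class Segment:
    t_start: float  # ns
    t_end: float
    T_start: float  # K
    T_end: float


@dataclass(frozen=True)
class TemperatureSchedule:
    """Piecewise-linear thermostat schedule in kelvin versus time in ns."""

    segments: tuple[Segment, ...]
    hold_after_end: bool = True

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        if self.segments[0].t_start != 0:
            raise ValueError("first segment must start at t = 0")
        for s1, s2 in zip(self.segments, self.segments[1:]):
            if s2.t_start != s1.t_end:
                raise ValueError("segments must be contiguous in time")
        for s in self.segments:
            if s.t_end <= s.t_start:
                raise ValueError("segments must be time-increasing")

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    @property
    def T_final(self) -> float:
        return self.segments[-1].T_end

    def temperature(self, t):
        """Thermostat temperature at time(s) ``t`` (ns); vectorised."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("negative time")
        if not self.hold_after_end and np.any(t_arr > self.t_end):
            raise ValueError(
                f"time beyond schedule end ({self.t_end} ns) with hold disabled"
            )
        knots_t = [self.segments[0].t_start]
        knots_T = [self.segments[0].T_start]
        for s in self.segments:
            knots_t.append(s.t_end)
            knots_T.append(s.T_end)
        out = np.interp(t_arr, knots_t, knots_T)
        return float(out) if np.isscalar(t) else out

    @classmethod
    def standard_heating(cls) -> "TemperatureSchedule":
        """Fast ramp -273 °C → -73 °C in 4 ns, slow ramp to 127 °C in 200 ns,
        then hold (°C mapped exactly as °C + 273.15)."""
        return cls(
            segments=(
                Segment(0.0, 4.0, c_to_k(-273.0), c_to_k(-73.0)),
                Segment(4.0, 204.0, c_to_k(-73.0), c_to_k(127.0)),
            ),
            hold_after_end=True,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "TemperatureSchedule":
        segs = tuple(
            Segment(s["t_start"], s["t_end"], s["T_start"], s["T_end"])
            for s in d["segments"]
        )
        return cls(segments=segs, hold_after_end=bool(d.get("hold_after_end", True)))

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end,
                 "T_start": s.T_start, "T_end": s.T_end}
                for s in self.segments
            ],
            "hold_after_end": self.hold_after_end,
        }


def frame_temperature(schedule: TemperatureSchedule, t):
    return schedule.temperature(t)


# ---------------------------------------------------------------------------
# trajectory container and IO


@dataclass
class HeatingTrajectory:
    """Frames of a heating run: coordinates (F, N, 3) Å, times (F,) ns."""

    coords: np.ndarray
    frame_times: np.ndarray
    residue_index: np.ndarray
    schedule: TemperatureSchedule
    atom_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("need at least two frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.coords.shape[0] != self.frame_times.shape[0]:
            raise ValueError("frame count mismatch")
        if self.coords.shape[1] != self.residue_index.shape[0]:
            raise ValueError("atom count mismatch")
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue indices must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_temperatures(self) -> np.ndarray:
        return self.schedule.temperature(self.frame_times)


def read_trajectory_pdb(
    path: str | Path,
    schedule: TemperatureSchedule,
    frame_times: Sequence[float] | None = None,
    dt: float | None = None,
) -> HeatingTrajectory:
    """Read a multi-model PDB (MODEL/ENDMDL frames) into a trajectory.

    Frame times come from ``frame_times`` or a uniform spacing ``dt`` (ns).
    """
    import biotite.structure.io.pdb as pdb

    stack = pdb.PDBFile.read(str(path)).get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if frame_times is None:
        if dt is None:
            raise ValueError("provide frame_times or dt")
        frame_times = np.arange(coords.shape[0]) * dt
    return HeatingTrajectory(
        coords=coords,
        frame_times=np.asarray(frame_times, dtype=float),
        residue_index=np.asarray(stack.res_id, dtype=int),
        schedule=schedule,
        atom_names=np.asarray(stack.atom_name),
    )


def read_trajectory_table(
    path: str | Path,
    schedule: TemperatureSchedule,
    frame_times: Sequence[float] | None = None,
    dt: float | None = None,
) -> HeatingTrajectory:
    """Read a whitespace-delimited per-frame coordinate table with columns
    ``frame atom x y z`` (optional trailing ``residue`` column; defaults to
    one residue per atom)."""
    df = pd.read_csv(str(path), sep=r"\s+", header=None, comment="#")
    if df.shape[1] == 5:
        df.columns = ["frame", "atom", "x", "y", "z"]
        df["residue"] = df["atom"]
    elif df.shape[1] == 6:
        df.columns = ["frame", "atom", "x", "y", "z", "residue"]
    else:
        raise ValueError("expected 5 or 6 whitespace-delimited columns")
    frames = np.sort(df["frame"].unique())
    atoms = np.sort(df[df["frame"] == frames[0]]["atom"].unique())
    coords = np.empty((len(frames), len(atoms), 3))
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("atom")
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
    res = df[df["frame"] == frames[0]].sort_values("atom")["residue"].to_numpy(int)
    if frame_times is None:
        if dt is None:
            raise ValueError("provide frame_times or dt")
        frame_times = np.arange(len(frames)) * dt
    return HeatingTrajectory(
        coords=coords,
        frame_times=np.asarray(frame_times, dtype=float),
        residue_index=res,
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# native contacts and order parameters


@dataclass(frozen=True)
class NativeContactSet:
    """Atom pairs in contact in the folded reference frame."""

    pairs: np.ndarray            # (M, 2) atom indices
    reference_distance: np.ndarray  # (M,)
    cutoff: float
    min_seq_separation: int

    def __len__(self) -> int:
        return self.pairs.shape[0]


def define_native_contacts(
    reference_coords: np.ndarray,
    residue_index: np.ndarray,
    cutoff: float = 4.5,
    min_seq_separation: int = 4,
) -> NativeContactSet:
    """All atom pairs within ``cutoff`` whose residues are at least
    ``min_seq_separation`` apart in sequence.

    Defaults are the all-heavy-atom convention (4.5 Å, separation 4); for
    Cα-only models use ``cutoff=8.0``.
    """
    coords = np.asarray(reference_coords, dtype=float)
    res = np.asarray(residue_index, dtype=int)
    if len(np.unique(res)) < 2:
        raise ValueError("reference needs at least two residues")
    tree = cKDTree(coords)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    if raw.size:
        keep = np.abs(res[raw[:, 0]] - res[raw[:, 1]]) >= min_seq_separation
        pairs = raw[keep]
    else:
        pairs = raw.reshape(0, 2)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return NativeContactSet(
        pairs=pairs[order],
        reference_distance=d[order],
        cutoff=cutoff,
        min_seq_separation=min_seq_separation,
    )


def contact_fraction_profile(
    traj: HeatingTrajectory,
    contacts: NativeContactSet,
    retention: str = "cutoff",
    retention_lambda: float = 1.2,
) -> np.ndarray:
    """Per-frame fraction Q of native contacts retained.

    ``retention='cutoff'`` keeps a contact while its distance stays within
    the defining cutoff; ``retention='lambda'`` uses λ × reference distance
    instead (conventions differ between analysis packages).
    """
    if len(contacts) == 0:
        raise ValueError("empty native-contact set")
    i, j = contacts.pairs[:, 0], contacts.pairs[:, 1]
    d = np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :], axis=2)
    if retention == "cutoff":
        threshold = contacts.cutoff
    elif retention == "lambda":
        threshold = retention_lambda * contacts.reference_distance
    else:
        raise ValueError(f"unknown retention mode {retention!r}")
    return (d <= threshold).mean(axis=1)


def rg_profile(traj: HeatingTrajectory, masses: np.ndarray | None = None) -> np.ndarray:
    """Per-frame radius of gyration (Å); unweighted unless masses given."""
    return radius_of_gyration(traj.coords, masses)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None):
    """Rg of (N, 3) coordinates or per-frame Rg of an (F, N, 3) stack."""
    c = np.asarray(coords, dtype=float)
    single = c.ndim == 2
    if single:
        c = c[None]
    if masses is None:
        w = np.ones(c.shape[1])
    else:
        w = np.asarray(masses, dtype=float)
    w = w / w.sum()
    centroid = np.einsum("fna,n->fa", c, w)
    sq = ((c - centroid[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt(np.einsum("fn,n->f", sq, w))
    return float(rg[0]) if single else rg


def moving_mean(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > x.size:
        raise ValueError("window longer than series")
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


# ---------------------------------------------------------------------------
# Tm estimation


#: criterion presets: (threshold, direction)
CRITERIA = {
    "contacts_q80": (0.8, "falls_below"),
    "rg_gt_14": (14.0, "exceeds"),
}


@dataclass(frozen=True)
class TmResult:
    tm_K: float | None
    censored: bool
    crossing_time_ns: float | None = None
    post_ramp: bool = False

    @property
    def tm_C(self) -> float | None:
        return None if self.tm_K is None else k_to_c(self.tm_K)


def estimate_tm(
    profile: np.ndarray,
    traj: HeatingTrajectory,
    threshold: float,
    direction: str = "falls_below",
    window: int = 51,
) -> TmResult:
    """Temperature at the first crossing of the smoothed profile.

    The profile is smoothed with a centred moving mean, the first crossing
    through ``threshold`` in the stated direction is located, the crossing
    time is interpolated linearly between the bracketing frames, and the
    schedule converts it to kelvin.  No crossing → censored.  Crossings
    after the ramp has ended report the hold temperature with a post-ramp
    flag (the schedule is constant there, so the temperature is exact but
    uninformative about rate).
    """
    x = moving_mean(np.asarray(profile, dtype=float), window)
    if x.shape[0] != traj.n_frames:
        raise ValueError("profile not aligned to trajectory frames")
    if direction == "falls_below":
        beyond = x < threshold
    elif direction == "exceeds":
        beyond = x > threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")

    if not beyond.any():
        return TmResult(tm_K=None, censored=True)
    k = int(np.argmax(beyond))
    t = traj.frame_times
    if k == 0:
        t_cross = float(t[0])
    else:
        x0, x1 = x[k - 1], x[k]
        frac = 0.0 if x1 == x0 else (threshold - x0) / (x1 - x0)
        t_cross = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    tm = float(traj.schedule.temperature(t_cross))
    post_ramp = t_cross > traj.schedule.t_end
    return TmResult(tm_K=tm, censored=False, crossing_time_ns=t_cross,
                    post_ramp=post_ramp)


def melt_tm(
    traj: HeatingTrajectory,
    contacts: NativeContactSet | None = None,
    criterion: str = "both",
    window: int = 51,
    contact_cutoff: float = 8.0,
    min_seq_separation: int = 4,
) -> dict[str, TmResult]:
    """Run one or both melting criteria on a trajectory.

    Native contacts default to the first frame as folded reference with the
    Cα convention (8 Å) since synthetic fixtures are Cα-only.
    """
    out: dict[str, TmResult] = {}
    wanted = list(CRITERIA) if criterion == "both" else [criterion]
    for name in wanted:
        threshold, direction = CRITERIA[name]
        if name == "contacts_q80":
            cs = contacts or define_native_contacts(
                traj.coords[0], traj.residue_index,
                cutoff=contact_cutoff, min_seq_separation=min_seq_separation,
            )
            profile = contact_fraction_profile(traj, cs)
        else:
            profile = rg_profile(traj)
        out[name] = estimate_tm(profile, traj, threshold, direction, window)
    return out


def window_temperature_span(
    traj: HeatingTrajectory, window: int, at_time: float | None = None
) -> float:
    """Temperature span covered by one smoothing window — the resolution
    limit of a crossing estimate.

    With ``at_time`` the span is evaluated around the nearest frame (use the
    crossing time); otherwise the median span over all frames is returned.
    """
    T = traj.frame_temperatures()
    half = window // 2
    if half == 0:
        return 0.0
    spans = np.array([
        T[min(k + half, len(T) - 1)] - T[max(k - half, 0)] for k in range(len(T))
    ])
    if at_time is None:
        return float(np.median(spans))
    k = int(np.argmin(np.abs(traj.frame_times - at_time)))
    return float(spans[k])


# ---------------------------------------------------------------------------
# aggregation and comparison


@dataclass(frozen=True)
class MeltingEstimate:
    per_repeat_Tm: tuple[float, ...]
    criterion: str
    mean_Tm: float
    sd_Tm: float
    censored: int

    @property
    def n(self) -> int:
        return len(self.per_repeat_Tm)


def aggregate_repeats(
    tms: Sequence[float | TmResult | None], criterion: str = "contacts_q80"
) -> MeltingEstimate:
    """Sample mean and SD (n-1) over uncensored repeats; censored counted."""
    values: list[float] = []
    censored = 0
    for t in tms:
        if isinstance(t, TmResult):
            t = t.tm_K if not t.censored else None
        if t is None:
            censored += 1
        else:
            values.append(float(t))
    if not values:
        raise ValueError("all repeats censored; no Tm to aggregate")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return MeltingEstimate(
        per_repeat_Tm=tuple(values),
        criterion=criterion,
        mean_Tm=float(arr.mean()),
        sd_Tm=sd,
        censored=censored,
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def compare_tm_groups(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sided Student's t test between two groups.

    Each group is either a sample sequence or a ``(mean, sd, n)`` summary
    triplet (so published mean/SD rows can be compared directly).  Zero
    pooled variance is degenerate: p = 1 for equal means, p = 0 otherwise.
    """

    def as_stats(g):
        if isinstance(g, tuple) and len(g) == 3 and np.isscalar(g[0]):
            return float(g[0]), float(g[1]), int(g[2])
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("need n >= 2 per group")
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = as_stats(a)
    m2, s2, n2 = as_stats(b)
    if s1 == 0 and s2 == 0:
        df = n1 + n2 - 2
        if m1 == m2:
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(t=float("inf"), df=df, p=0.0, degenerate=True)
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:  # Welch-Satterthwaite
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))
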