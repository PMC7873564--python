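"""Geometric analysis of receptor/ligand complex poses.

The receptor Ig-like domain is docked onto one two-chain subunit of the
pentameric IgM-Fc disc; this module is the gatekeeper for such poses.  It
counts residue-residue contacts, evaluates the interface constraint set
(required and forbidden interface residues, excluded bystander chains,
dominance of the membrane-proximal Cµ4 domain, glycan clearance, C-terminus
accessibility, dual-occupancy sterics), tiles the docked pair over the
remaining subunits by Cα superposition, and calibrates docking scores
against log10 binding constants.

Poses are inputs — no docking search or minimisation happens here.
Residues are addressed as (chain id, author residue number); insertion
codes are not supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

ResidueRef = tuple[str, int]

#: default heavy-atom interface cutoff (Å)
INTERFACE_CUTOFF = 5.0
#: default heavy-atom clash threshold (Å)
CLASH_MIN_DIST = 2.5
#: default pseudo-glycan exclusion radius (Å)
GLYCAN_RADIUS = 6.0
#: default clearance for an exposed C-terminus (Å)
CTERM_CLEARANCE = 8.0


def parse_residue_ref(text: str) -> ResidueRef:
    """Parse a ``CHAIN:RESNUM`` residue reference such as ``C:510``."""
    chain, _, num = text.partition(":")
    if not chain or not num:
        raise ValueError(f"bad residue reference {text!r} (expected CHAIN:NUM)")
    return chain, int(num)


# ---------------------------------------------------------------------------
# structure container


@dataclass
class Structure:
    """Flat atom-array structure: parallel arrays over atoms."""

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        for arr in (self.chain_id, self.res_id, self.res_name,
                    self.atom_name, self.element):
            if arr.shape[0] != n:
                raise ValueError("atom array length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue, atom name) triple")

    def __len__(self) -> int:
        return self.coords.shape[0]

    # -- selection ---------------------------------------------------------

    def mask(
        self,
        chains: Iterable[str] | None = None,
        residues: Iterable[int] | None = None,
        heavy_only: bool = True,
    ) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chains is not None:
            m &= np.isin(self.chain_id, list(chains))
        if residues is not None:
            m &= np.isin(self.res_id, list(residues))
        if heavy_only:
            m &= self.element != "H"
        return m

    def subset(self, mask_or_chains) -> "Structure":
        m = (
            self.mask(chains=mask_or_chains, heavy_only=False)
            if not isinstance(mask_or_chains, np.ndarray)
            else mask_or_chains
        )
        return Structure(
            chain_id=self.chain_id[m],
            res_id=self.res_id[m],
            res_name=self.res_name[m],
            atom_name=self.atom_name[m],
            element=self.element[m],
            coords=self.coords[m],
        )

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def residue_atoms(self, ref: ResidueRef, heavy_only: bool = True) -> np.ndarray:
        chain, num = ref
        m = (self.chain_id == chain) & (self.res_id == num)
        if heavy_only:
            m &= self.element != "H"
        if not m.any():
            raise KeyError(f"residue {chain}:{num} not found")
        return self.coords[m]

    def has_residue(self, ref: ResidueRef) -> bool:
        chain, num = ref
        return bool(np.any((self.chain_id == chain) & (self.res_id == num)))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return Structure(
            chain_id=self.chain_id.copy(),
            res_id=self.res_id.copy(),
            res_name=self.res_name.copy(),
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        m = self.mask(heavy_only=heavy_only)
        return self.coords[m].mean(axis=0)

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_pdb(cls, path: str | Path, model: int = 1) -> "Structure":
        import biotite.structure.io.pdb as pdb

        arr = pdb.PDBFile.read(str(path)).get_structure(model=model)
        return cls(
            chain_id=np.asarray(arr.chain_id),
            res_id=np.asarray(arr.res_id),
            res_name=np.asarray(arr.res_name),
            atom_name=np.asarray(arr.atom_name),
            element=np.asarray(arr.element),
            coords=np.asarray(arr.coord, dtype=float),
        )

    def to_pdb(self, path: str | Path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        arr = struc.AtomArray(len(self))
        arr.chain_id = self.chain_id
        arr.res_id = self.res_id
        arr.res_name = self.res_name
        arr.atom_name = self.atom_name
        arr.element = self.element
        arr.coord = self.coords.astype(np.float32)
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    @classmethod
    def concat(cls, parts: Sequence["Structure"]) -> "Structure":
        return cls(
            chain_id=np.concatenate([p.chain_id for p in parts]),
            res_id=np.concatenate([p.res_id for p in parts]),
            res_name=np.concatenate([p.res_name for p in parts]),
            atom_name=np.concatenate([p.atom_name for p in parts]),
            element=np.concatenate([p.element for p in parts]),
            coords=np.concatenate([p.coords for p in parts]),
        )


# ---------------------------------------------------------------------------
# contacts


@dataclass(frozen=True)
class InterfaceReport:
    """Residue-pair contacts across an interface with minimum distances."""

    pairs: dict[tuple[ResidueRef, ResidueRef], float]
    cutoff: float

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def residues_a(self) -> set[ResidueRef]:
        return {a for a, _ in self.pairs}

    def residues_b(self) -> set[ResidueRef]:
        return {b for _, b in self.pairs}

    def involves(self, ref: ResidueRef) -> bool:
        return any(ref in pair for pair in self.pairs)


def residue_contacts(
    a: Structure, b: Structure, cutoff: float = INTERFACE_CUTOFF
) -> InterfaceReport:
    """Residue pairs with any heavy-atom pair across the interface ≤ cutoff.

    Symmetric in a/b up to pair orientation; minimum inter-atomic distance
    is reported per residue pair.
    """
    ma, mb = a.mask(heavy_only=True), b.mask(heavy_only=True)
    if not ma.any() or not mb.any():
        raise ValueError("empty selection")
    ca, cb = a.coords[ma], b.coords[mb]
    keys_a = list(zip(a.chain_id[ma], a.res_id[ma]))
    keys_b = list(zip(b.chain_id[mb], b.res_id[mb]))
    if set(keys_a) & set(keys_b):
        raise ValueError("selections must be disjoint")
    tree = cKDTree(cb)
    pairs: dict[tuple[ResidueRef, ResidueRef], float] = {}
    neighbors = tree.query_ball_point(ca, cutoff)
    for ia, hits in enumerate(neighbors):
        if not hits:
            continue
        ra = (str(keys_a[ia][0]), int(keys_a[ia][1]))
        d = np.linalg.norm(cb[hits] - ca[ia], axis=1)
        for ib, dist in zip(hits, d):
            rb = (str(keys_b[ib][0]), int(keys_b[ib][1]))
            key = (ra, rb)
            if key not in pairs or dist < pairs[key]:
                pairs[key] = float(dist)
    return InterfaceReport(pairs=pairs, cutoff=cutoff)


def domain_contact_fraction(
    report: InterfaceReport,
    regions: dict[str, list[tuple[str, int, int]]],
) -> dict[str, float]:
    """Fraction of interface contacts falling in each named ligand region.

    Regions are lists of (chain, start, end) ranges over the *b* side of the
    report; contacts outside every region are pooled under ``other``.
    Fractions sum to 1 over assigned regions plus other.
    """
    counts = {name: 0 for name in regions}
    counts["other"] = 0
    for (_, (chain, num)) in report.pairs:
        for name, ranges in regions.items():
            if any(c == chain and lo <= num <= hi for c, lo, hi in ranges):
                counts[name] += 1
                break
        else:
            counts["other"] += 1
    total = sum(counts.values())
    if total == 0:
        return {name: 0.0 for name in counts}
    return {name: n / total for name, n in counts.items()}


# ---------------------------------------------------------------------------
# constraints


@dataclass(frozen=True)
class DockConstraints:
    """The interface constraint set applied to candidate docking poses.

    Required receptor loops (CDR2/DE-loop/CDR3 residues) and the ligand Cµ4
    glutamine must be at the interface; CDR1 residues and the free-face
    tyrosine must not be; bystander chains from adjacent subunits may not
    contribute contacts; most contacts must fall in Cµ4 (strict > fraction);
    and the conserved Cµ3 glycosylation site must stay clear.
    """

    required_receptor: tuple[ResidueRef, ...]
    required_ligand: tuple[ResidueRef, ...]
    forbidden_receptor: tuple[ResidueRef, ...]
    excluded_chains: tuple[str, ...] = ()
    domain_regions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    dominant_region: str | None = None
    min_fraction_dominant: float = 0.75
    glyco_site: ResidueRef | None = None
    glyco_radius: float = GLYCAN_RADIUS

    def __post_init__(self) -> None:
        if set(self.required_receptor) & set(self.forbidden_receptor):
            raise ValueError("required and forbidden receptor residues overlap")
        if not 0 < self.min_fraction_dominant <= 1:
            raise ValueError("min_fraction_dominant must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "DockConstraints":
        regions = {
            name: [tuple(r) for r in ranges]
            for name, ranges in d.get("domain_regions", {}).items()
        }
        return cls(
            required_receptor=tuple(parse_residue_ref(r) for r in d["required_receptor"]),
            required_ligand=tuple(parse_residue_ref(r) for r in d["required_ligand"]),
            forbidden_receptor=tuple(parse_residue_ref(r) for r in d["forbidden_receptor"]),
            excluded_chains=tuple(d.get("excluded_chains", ())),
            domain_regions=regions,
            dominant_region=d.get("dominant_region"),
            min_fraction_dominant=float(d.get("min_fraction_dominant", 0.75)),
            glyco_site=(parse_residue_ref(d["glyco_site"]) if d.get("glyco_site") else None),
            glyco_radius=float(d.get("glyco_radius", GLYCAN_RADIUS)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DockConstraints":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ConstraintItem:
    name: str
    passed: bool
    evidence: str


@dataclass(frozen=True)
class ConstraintReport:
    passed: bool
    items: tuple[ConstraintItem, ...]
    interface: InterfaceReport

    def item(self, name: str) -> ConstraintItem:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)


def check_constraints(
    complex_: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    constraints: DockConstraints,
    cutoff: float = INTERFACE_CUTOFF,
) -> ConstraintReport:
    """Evaluate the interface constraint set on one pose.

    PASS requires every required residue at the interface, no forbidden
    receptor residue at the interface, and zero contacts contributed by any
    excluded chain.  Each constraint is reported with evidence distances.
    """
    receptor = complex_.subset(list(receptor_chains))
    ligand = complex_.subset(list(ligand_chains))
    for ref in (
        constraints.required_receptor + constraints.forbidden_receptor
    ):
        if not receptor.has_residue(ref):
            raise KeyError(f"receptor residue {ref[0]}:{ref[1]} not resolvable")
    for ref in constraints.required_ligand:
        if not ligand.has_residue(ref):
            raise KeyError(f"ligand residue {ref[0]}:{ref[1]} not resolvable")

    report = residue_contacts(receptor, ligand, cutoff)
    items: list[ConstraintItem] = []

    def min_dist(ref: ResidueRef, other: Structure) -> float:
        a = complex_.residue_atoms(ref)
        tree = cKDTree(other.coords[other.mask(heavy_only=True)])
        return float(tree.query(a)[0].min())

    for ref in constraints.required_receptor:
        ok = report.involves(ref)
        items.append(ConstraintItem(
            name=f"required_interface:{ref[0]}:{ref[1]}", passed=ok,
            evidence=f"min heavy-atom distance to ligand {min_dist(ref, ligand):.2f} A",
        ))
    for ref in constraints.required_ligand:
        ok = report.involves(ref)
        items.append(ConstraintItem(
            name=f"required_interface:{ref[0]}:{ref[1]}", passed=ok,
            evidence=f"min heavy-atom distance to receptor {min_dist(ref, receptor):.2f} A",
        ))
    for ref in constraints.forbidden_receptor:
        ok = not report.involves(ref)
        items.append(ConstraintItem(
            name=f"forbidden_interface:{ref[0]}:{ref[1]}", passed=ok,
            evidence=f"min heavy-atom distance to ligand {min_dist(ref, ligand):.2f} A",
        ))
    for chain in constraints.excluded_chains:
        sub = complex_.subset([chain])
        if len(sub) == 0:
            items.append(ConstraintItem(
                name=f"excluded_chain:{chain}", passed=True, evidence="chain absent"))
            continue
        rep = residue_contacts(receptor, sub, cutoff)
        items.append(ConstraintItem(
            name=f"excluded_chain:{chain}", passed=rep.n_contacts == 0,
            evidence=f"{rep.n_contacts} contacts to excluded chain",
        ))
    passed = all(it.passed for it in items)
    return ConstraintReport(passed=passed, items=tuple(items), interface=report)


# ---------------------------------------------------------------------------
# superposition, clash, accessibility


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation + translation mapping mobile → target.

    Returns (R, t, rmsd) with ``x' = R @ x + t``; the rotation is always
    proper (det = +1), so mirror images keep a residual RMSD.  Degenerate
    (coincident or collinear) point sets are rejected.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need matching (N, 3) arrays with N >= 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


@dataclass(frozen=True)
class ClashResult:
    clash: bool
    n_pairs: int
    min_distance: float


def clash_check(
    a_coords: np.ndarray, b_coords: np.ndarray, min_dist: float = CLASH_MIN_DIST
) -> ClashResult:
    """Steric clash iff any heavy-atom pair across the two sets is closer
    than ``min_dist``."""
    A = np.atleast_2d(np.asarray(a_coords, dtype=float))
    B = np.atleast_2d(np.asarray(b_coords, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("empty coordinate set")
    tree = cKDTree(B)
    dmin = float(tree.query(A)[0].min())
    n = 0
    if dmin < min_dist:
        # ball query includes the boundary; clash pairs are strictly inside
        for p, hits in zip(A, tree.query_ball_point(A, min_dist)):
            if hits:
                n += int((np.linalg.norm(B[hits] - p, axis=1) < min_dist).sum())
    return ClashResult(clash=dmin < min_dist, n_pairs=n, min_distance=dmin)


def glycan_filter(
    complex_: Structure,
    site: ResidueRef,
    receptor_chains: Sequence[str],
    radius: float = GLYCAN_RADIUS,
) -> bool:
    """PASS iff no receptor heavy atom intrudes into a pseudo-glycan sphere
    centred on the glycosylation site's side-chain tip (the heavy atom
    farthest from Cα; Cα itself with a warning when no side chain exists).
    """
    atoms = complex_.residue_atoms(site)
    chain, num = site
    m = (complex_.chain_id == chain) & (complex_.res_id == num)
    names = complex_.atom_name[m]
    coords = complex_.coords[m]
    side = [i for i, nm in enumerate(names)
            if nm not in ("N", "CA", "C", "O", "CA ")]
    if side:
        ca = coords[list(names).index("CA")] if "CA" in names else coords.mean(axis=0)
        tip = coords[side[int(np.argmax(np.linalg.norm(coords[side] - ca, axis=1)))]]
    else:
        warnings.warn(
            f"glycan site {chain}:{num} has no side-chain atoms; using CA",
            stacklevel=2,
        )
        tip = coords[0] if "CA" not in names else coords[list(names).index("CA")]
    receptor = complex_.subset(list(receptor_chains))
    rc = receptor.coords[receptor.mask(heavy_only=True)]
    return bool(np.all(np.linalg.norm(rc - tip, axis=1) > radius))


def cterm_accessibility(
    receptor: Structure,
    environment: Structure,
    threshold: float = CTERM_CLEARANCE,
) -> bool:
    """Is the receptor C-terminus free to connect to a membrane stalk?

    Accessible iff (a) no environment heavy atom lies within ``threshold``
    of the C-terminal residue's Cα (last atom of the residue if no Cα), and
    (b) the Cα lies in the half-space on the far side of the receptor
    centroid from the environment centroid (pointing away from the ligand).
    """
    if len(receptor) == 0:
        raise ValueError("empty receptor")
    last_res = int(receptor.res_id.max())
    m = receptor.res_id == last_res
    names = receptor.atom_name[m]
    coords = receptor.coords[m]
    ca = coords[list(names).index("CA")] if "CA" in names else coords[-1]
    env_heavy = environment.coords[environment.mask(heavy_only=True)]
    if env_heavy.size:
        if float(cKDTree(env_heavy).query(ca)[0]) < threshold:
            return False
        outward = receptor.centroid() - environment.centroid()
    else:
        outward = np.zeros(3)
    return bool(np.dot(ca - receptor.centroid(), outward) >= -1e-9)


# ---------------------------------------------------------------------------
# pentamer tiling


@dataclass(frozen=True)
class Placement:
    receptor: Structure
    source_subunit: int
    rotation: np.ndarray
    translation: np.ndarray
    clash: bool
    accessible: bool


@dataclass(frozen=True)
class PlacementSet:
    placements: tuple[Placement, ...]

    @property
    def n(self) -> int:
        return len(self.placements)

    @property
    def accessible_count(self) -> int:
        return sum(p.accessible and not p.clash for p in self.placements)

    @property
    def clash_count(self) -> int:
        return sum(p.clash for p in self.placements)


def _subunit_ca(structure: Structure, chains: Sequence[str]) -> np.ndarray:
    sub = structure.subset(list(chains))
    m = sub.atom_name == "CA"
    order = np.lexsort((sub.res_id[m], sub.chain_id[m]))
    return sub.coords[m][order]


def tile_pentamer(
    pentamer: Structure,
    docked_receptors: Sequence[Structure],
    subunit_chain_pairs: Sequence[Sequence[str]],
    clash_min_dist: float = CLASH_MIN_DIST,
    cterm_threshold: float = CTERM_CLEARANCE,
) -> PlacementSet:
    """Tile docked receptor domains over every subunit of the disc.

    The first chain pair is the source subunit carrying ``docked_receptors``.
    For every other subunit the source Cα set is superposed onto it (Kabsch)
    and the receptors carried along.  Every placement — including the source
    pair — receives a clash verdict (against the pentamer and all other
    placements) and a C-terminus accessibility verdict against the pentamer.
    """
    source = subunit_chain_pairs[0]
    src_ca = _subunit_ca(pentamer, source)
    raw: list[tuple[Structure, int, np.ndarray, np.ndarray]] = []
    for rec in docked_receptors:
        raw.append((rec, 0, np.eye(3), np.zeros(3)))
    for k, chains in enumerate(subunit_chain_pairs[1:], start=1):
        tgt_ca = _subunit_ca(pentamer, chains)
        if tgt_ca.shape != src_ca.shape:
            raise ValueError(
                f"subunit {k}: Cα count {tgt_ca.shape[0]} does not match "
                f"source {src_ca.shape[0]}"
            )
        R, t, _ = kabsch_superpose(src_ca, tgt_ca)
        for rec in docked_receptors:
            raw.append((rec.transformed(R, t), k, R, t))

    pent_heavy = pentamer.coords[pentamer.mask(heavy_only=True)]
    placements: list[Placement] = []
    for i, (rec, sub, R, t) in enumerate(raw):
        rc = rec.coords[rec.mask(heavy_only=True)]
        clash = clash_check(rc, pent_heavy, clash_min_dist).clash
        for j, (other, *_rest) in enumerate(raw):
            if j == i or clash:
                continue
            oc = other.coords[other.mask(heavy_only=True)]
            if clash_check(rc, oc, clash_min_dist).clash:
                clash = True
        accessible = cterm_accessibility(rec, pentamer, cterm_threshold)
        placements.append(Placement(
            receptor=rec, source_subunit=sub, rotation=R, translation=t,
            clash=clash, accessible=accessible,
        ))
    return PlacementSet(placements=tuple(placements))


# ---------------------------------------------------------------------------
# affinity calibration


class AffinityCalibration:
    """Linear map between a docking score and log10 of the association
    constant Ka, fitted by least squares.

    Attributes set by :meth:`fit`: ``slope_``, ``intercept_`` (log10 Ka per
    score unit and at score 0).
    """

    slope_: float
    intercept_: float

    def fit(self, scores, ka) -> "AffinityCalibration":
        s = np.asarray(scores, dtype=float)
        k = np.asarray(ka, dtype=float)
        if s.size != k.size or s.size < 2:
            raise ValueError("need >= 2 (score, Ka) points")
        if np.any(k <= 0):
            raise ValueError("Ka values must be positive")
        if np.unique(s).size < 2:
            raise ValueError("need >= 2 distinct scores to fit a line")
        self.slope_, self.intercept_ = np.polyfit(s, np.log10(k), 1)
        self.slope_ = float(self.slope_)
        self.intercept_ = float(self.intercept_)
        return self

    def predict_log10_ka(self, score):
        return self.slope_ * np.asarray(score, dtype=float) + self.intercept_

    def predict(self, score):
        """Predicted Ka (M^-1) at a docking score."""
        out = 10.0 ** self.predict_log10_ka(score)
        return float(out) if np.isscalar(score) else out


def fit_affinity_calibration(points: Sequence[tuple[float, float]]) -> AffinityCalibration:
    scores, ka = zip(*points)
    return AffinityCalibration().fit(scores, ka)
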