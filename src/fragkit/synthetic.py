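"""Seeded synthetic inputs for every pipeline stage.

Each generator is a pure function of its spec (seed included): re-running
with the same spec reproduces byte-identical output. Every generator also
emits a ground-truth sidecar so downstream tests never re-derive truth from
the generated data itself.

What is emulated, and what is not:

* Ortholog families — per-position independent substitutions at a background
  rate, with a lower rate inside designated "site" positions; replacements
  are uniform over the 19 alternative amino acids. This reproduces the
  site-more-conserved-than-background signal that identity arithmetic must
  detect; it is not an evolutionary model (no phylogeny, no substitution
  matrix).
* Screen decks — a 1371-fragment library with 50 planted binders whose
  attenuation ratios sit below the call threshold by a stated margin, a
  subset competable at the cap site.
* Toy structures — line/helix/random-sphere residue geometries with a placed
  ligand, exact residue–ligand distance tables, and rigid-copy pairs with the
  applied transform recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .conservation import Alignment
from .errors import SpecError
from .nmr import ScreenRecord
from .structures import AtomRecord, LigandSelection, StructureModel, write_pdb

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Ortholog families


@dataclass(frozen=True)
class OrthologFamilySpec:
    """A reference sequence mutated into n_orthologs at two rates.

    ``p_global`` applies outside the site positions, ``p_site`` inside; for a
    conservation-enriched family 0 <= p_site <= p_global <= 1 (checked).
    ``indel_p`` is a per-position deletion probability (gap in the ortholog;
    the alignment stays columnar).
    """

    length: int = 220
    n_orthologs: int = 30
    p_global: float = 0.2
    p_site: float = 0.02
    site_positions: tuple[int, ...] = ()
    indel_p: float = 0.0
    seed: int = 0
    allow_inverted_rates: bool = False

    def __post_init__(self) -> None:
        for name in ("p_global", "p_site", "indel_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_site > self.p_global and not self.allow_inverted_rates:
            raise SpecError(
                f"p_site ({self.p_site}) > p_global ({self.p_global}) breaks the "
                "conservation-enriched family invariant"
            )
        if any(not (1 <= p <= self.length) for p in self.site_positions):
            raise ValueError("site positions must lie in [1, length]")


def generate_ortholog_family(spec: OrthologFamilySpec) -> tuple[Alignment, dict]:
    """Generate an aligned family plus a ground-truth sidecar.

    The reference record is first; ortholog ids are ``ortho001``.. . The truth
    dict records the reference sequence, site positions and the realised
    per-ortholog substitution/deletion counts.
    """
    rng = np.random.default_rng(spec.seed)
    ref = "".join(rng.choice(list(AMINO_ACIDS), size=spec.length))
    site = set(spec.site_positions)
    records = [("reference", ref)]
    truth_rows = []
    for i in range(spec.n_orthologs):
        chars = []
        n_sub = n_del = 0
        for pos1, aa in enumerate(ref, start=1):
            if spec.indel_p > 0 and rng.random() < spec.indel_p:
                chars.append("-")
                n_del += 1
                continue
            p = spec.p_site if pos1 in site else spec.p_global
            if p > 0 and rng.random() < p:
                alternatives = AMINO_ACIDS.replace(aa, "")
                chars.append(alternatives[rng.integers(len(alternatives))])
                n_sub += 1
            else:
                chars.append(aa)
        rid = f"ortho{i + 1:03d}"
        records.append((rid, "".join(chars)))
        truth_rows.append({"id": rid, "n_substitutions": n_sub, "n_deletions": n_del})
    truth = {
        "spec": asdict(spec),
        "reference": ref,
        "site_positions": sorted(site),
        "orthologs": truth_rows,
    }
    return Alignment(records=records, reference_id="reference"), truth


def alignment_to_fasta(alignment: Alignment, degap: bool = False) -> str:
    """Serialise aligned (or ungapped, degap=True) FASTA text."""
    chunks = []
    for rid, seq in alignment.records:
        if degap:
            seq = seq.replace("-", "")
        chunks.append(f">{rid}\n{seq}\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Screen decks


@dataclass(frozen=True)
class ScreenDeckSpec:
    """A fragment library with planted binders at stated attenuation.

    Binder and non-binder attenuation ratio ranges must be separated from the
    calling threshold ``tau`` by ``margin`` on either side (set
    ``allow_overlap=True`` to bypass, e.g. for robustness experiments).
    """

    n_library: int = 1371
    n_binders: int = 50
    binder_rho_range: tuple[float, float] = (0.2, 0.6)
    nonbinder_rho_range: tuple[float, float] = (0.9, 1.05)
    tau: float = 0.8
    margin: float = 0.1
    fraction_site1: float = 0.2
    cocktail_size: int = 4
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_binders > self.n_library:
            raise ValueError("n_binders cannot exceed n_library")
        if not (0.0 <= self.fraction_site1 <= 1.0):
            raise ValueError("fraction_site1 must lie in [0, 1]")
        if not self.allow_overlap:
            if self.binder_rho_range[1] > self.tau - self.margin:
                raise SpecError(
                    "binder rho range overlaps tau - margin; pass allow_overlap=True "
                    "to generate an ambiguous deck deliberately"
                )
            if self.nonbinder_rho_range[0] < self.tau + self.margin:
                raise SpecError(
                    "non-binder rho range overlaps tau + margin; pass "
                    "allow_overlap=True to generate an ambiguous deck deliberately"
                )


def generate_screen_deck(spec: ScreenDeckSpec) -> tuple[list[ScreenRecord], dict]:
    """Generate screen records plus a {fragment_id: truth} sidecar."""
    rng = np.random.default_rng(spec.seed)
    is_binder = np.zeros(spec.n_library, dtype=bool)
    binder_idx = rng.choice(spec.n_library, size=spec.n_binders, replace=False)
    is_binder[binder_idx] = True
    n_site1 = int(round(spec.fraction_site1 * spec.n_binders))
    site1_idx = set(rng.choice(binder_idx, size=n_site1, replace=False)) if n_site1 else set()

    records: list[ScreenRecord] = []
    truth: dict[str, dict] = {}
    for i in range(spec.n_library):
        frag = f"F{i + 1:04d}"
        cocktail = f"C{i // spec.cocktail_size + 1:04d}"
        i_ref = float(rng.uniform(5e4, 2e5))
        if is_binder[i]:
            rho = float(rng.uniform(*spec.binder_rho_range))
            if i in site1_idx:
                rho_comp = float(rng.uniform(0.9, 1.0))
            else:
                rho_comp = float(np.clip(rho + rng.uniform(-0.03, 0.03), 0.0, None))
        else:
            rho = float(rng.uniform(*spec.nonbinder_rho_range))
            rho_comp = None
        records.append(
            ScreenRecord(
                fragment_id=frag,
                cocktail_id=cocktail,
                i_ref=i_ref,
                i_protein=rho * i_ref,
                i_competitor=None if rho_comp is None else rho_comp * i_ref,
            )
        )
        truth[frag] = {
            "binder": bool(is_binder[i]),
            "site1": bool(i in site1_idx),
            "rho": rho,
        }
    return records, truth


# ---------------------------------------------------------------------------
# Toy structures


@dataclass(frozen=True)
class ToyStructureSpec:
    """A toy protein with a placed ligand and known distance geometry.

    geometry: 'line' (single-CA residues along x), 'helix' (full N/CA/C/O
    backbone on an alpha-helical curve) or 'random-sphere' (single-CA
    residues at random positions in a shell around the ligand).
    """

    n_residues: int = 10
    geometry: str = "line"
    spacing: float = 1.0
    ligand_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("line", "helix", "random-sphere"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 1:
            raise ValueError("need at least one residue")


@dataclass
class ToyStructure:
    """Generated structure plus generator-side ground truth."""

    model: StructureModel
    pdb_text: str
    ligand: LigandSelection
    distance_table: dict[int, float]

    def truth_json(self) -> str:
        return json.dumps(
            {
                "ligand": asdict(self.ligand),
                "min_distances": {str(k): v for k, v in self.distance_table.items()},
            },
            indent=2,
        )


def _backbone_offsets(angle: float) -> dict[str, np.ndarray]:
    """Rough backbone atom offsets from CA, rotated with the helix phase."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    base = {
        "N": np.array([-1.2, 0.6, -0.4]),
        "C": np.array([1.1, 0.7, 0.3]),
        "O": np.array([1.6, 1.6, 0.9]),
    }
    return {name: rot @ off for name, off in base.items()}


def generate_toy_structure(spec: ToyStructureSpec) -> ToyStructure:
    """Build a parseable PDB toy with its exact residue–ligand distance table."""
    rng = np.random.default_rng(spec.seed)
    lig = np.asarray(spec.ligand_position, dtype=float)

    atoms: list[AtomRecord] = []
    serial = 1

    def add(name, resname, resnum, xyz, hetero=False, element=None):
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                altloc="",
                residue_name=resname,
                chain_id=spec.chain_id,
                residue_number=resnum,
                insertion_code="",
                xyz=tuple(float(v) for v in xyz),
                occupancy=1.0,
                element=element or name[0],
                is_hetero=hetero,
            )
        )
        serial += 1

    per_residue: dict[int, list[np.ndarray]] = {}
    for i in range(spec.n_residues):
        resnum = i + 1
        if spec.geometry == "line":
            ca = lig + np.array([spec.spacing * resnum, 0.0, 0.0])
            add("CA", "GLY", resnum, ca, element="C")
            per_residue[resnum] = [ca]
        elif spec.geometry == "random-sphere":
            while True:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                radius = rng.uniform(2.0, 12.0)
                ca = lig + radius * direction
                if all(
                    np.linalg.norm(ca - p) > 0.5
                    for pts in per_residue.values()
                    for p in pts
                ):
                    break
            add("CA", "GLY", resnum, ca, element="C")
            per_residue[resnum] = [ca]
        else:  # helix
            angle = np.deg2rad(100.0) * i
            ca = lig + np.array(
                [2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i + 3.0]
            )
            offs = _backbone_offsets(angle)
            coords = [ca]
            add("N", "ALA", resnum, ca + offs["N"], element="N")
            add("CA", "ALA", resnum, ca, element="C")
            add("C", "ALA", resnum, ca + offs["C"], element="C")
            add("O", "ALA", resnum, ca + offs["O"], element="O")
            coords += [ca + offs[n] for n in ("N", "C", "O")]
            per_residue[resnum] = coords

    ligand_resnum = spec.n_residues + 1
    add("C1", "LIG", ligand_resnum, lig, hetero=True, element="C")

    distance_table = {
        resnum: float(min(np.linalg.norm(p - lig) for p in pts))
        for resnum, pts in per_residue.items()
    }
    model = StructureModel(atoms=atoms, identifier=f"toy-{spec.geometry}-{spec.seed}")
    return ToyStructure(
        model=model,
        pdb_text=write_pdb(model),
        ligand=LigandSelection(
            chain_id=spec.chain_id, residue_name="LIG", residue_number=ligand_resnum
        ),
        distance_table=distance_table,
    )


def rigid_copy(
    model: StructureModel, seed: int = 0, translation_scale: float = 10.0
) -> tuple[StructureModel, np.ndarray, np.ndarray]:
    """A rigidly rotated + translated copy; returns (copy, rotation, translation)."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    atoms = [
        AtomRecord(
            serial=a.serial,
            name=a.name,
            altloc=a.altloc,
            residue_name=a.residue_name,
            chain_id=a.chain_id,
            residue_number=a.residue_number,
            insertion_code=a.insertion_code,
            xyz=tuple(R @ np.asarray(a.xyz) + t),
            occupancy=a.occupancy,
            element=a.element,
            is_hetero=a.is_hetero,
        )
        for a in model.atoms
    ]
    return (
        StructureModel(atoms=atoms, identifier=f"{model.identifier}-rigidcopy"),
        R,
        t,
    )


def displace_atoms(
    model: StructureModel, displacements: np.ndarray
) -> StructureModel:
    """Per-atom displaced copy (for planting a known deformation RMSD)."""
    displacements = np.asarray(displacements, dtype=float)
    if displacements.shape != (len(model.atoms), 3):
        raise ValueError("one 3-vector displacement per atom required")
    atoms = [
        AtomRecord(
            serial=a.serial,
            name=a.name,
            altloc=a.altloc,
            residue_name=a.residue_name,
            chain_id=a.chain_id,
            residue_number=a.residue_number,
            insertion_code=a.insertion_code,
            xyz=tuple(np.asarray(a.xyz) + d),
            occupancy=a.occupancy,
            element=a.element,
            is_hetero=a.is_hetero,
        )
        for a, d in zip(model.atoms, displacements)
    ]
    return StructureModel(atoms=atoms, identifier=f"{model.identifier}-displaced")
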