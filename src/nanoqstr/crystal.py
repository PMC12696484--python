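"""Crystal unit cells and spherical nanoparticle construction.

A nanoparticle model is built in three steps: parse a CIF unit cell,
replicate it into a supercell large enough to contain the requested sphere,
and keep the atoms within ``diameter/2`` of a centre point.  Atoms within a
fixed depth of the nominal surface form the *shell* region; the rest form
the *core*.  This core–shell partition is what the region-resolved
descriptors operate on.

CIF reading covers the small-molecule/inorganic dialect: cell parameters,
symmetry operator loops (``_symmetry_equiv_pos_as_xyz`` or
``_space_group_symop_operation_as_xyz``; P1 assumed when absent) and
fractional ``_atom_site`` loops.  Anisotropic displacement and charge tags
are ignored.  Species labels are normalised to bare element symbols.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import CifParseError, EmptyParticleError, ValidationError

#: Tolerance (Å) below which two symmetry images count as the same site.
MERGE_TOL = 0.01

#: Default shell depth (Å): atoms within this distance of the nominal
#: surface belong to the shell region.
DEFAULT_SHELL_DEPTH = 4.0

_CELL_TAGS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)

_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_as_xyz")

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)")


def normalise_species(label: str) -> str:
    """Strip site numbering and oxidation suffixes: ``Fe3+``/``Fe1`` -> ``Fe``."""
    m = _ELEMENT_RE.match(label.strip())
    if not m:
        raise CifParseError(f"cannot read an element symbol from site label {label!r}")
    return m.group(1)


def lattice_from_parameters(a, b, c, alpha, beta, gamma) -> np.ndarray:
    """Cell lengths (Å) and angles (deg) -> row-vector lattice matrix.

    Standard crystallographic convention: **a** along x, **b** in the
    xy-plane.
    """
    al, be, ga = np.radians([alpha, beta, gamma])
    v1 = np.array([a, 0.0, 0.0])
    v2 = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz_sq = c**2 - cx**2 - cy**2
    if cz_sq <= 0:
        raise ValidationError("cell angles give a non-positive cell volume")
    v3 = np.array([cx, cy, np.sqrt(cz_sq)])
    return np.vstack([v1, v2, v3])


@dataclass
class UnitCell:
    """A crystal unit cell after symmetry expansion.

    ``lattice`` holds the three lattice vectors as rows (Å); ``frac_coords``
    are wrapped into [0, 1); ``species`` are bare element symbols.
    """

    lattice: np.ndarray
    species: list[str]
    frac_coords: np.ndarray
    phase_id: str = ""
    symmetry_ops: list[str] = field(default_factory=lambda: ["x,y,z"])

    def __post_init__(self):
        self.lattice = np.asarray(self.lattice, dtype=float)
        self.frac_coords = np.atleast_2d(np.asarray(self.frac_coords, dtype=float))
        if self.volume <= 0:
            raise ValidationError(
                f"lattice vectors of {self.phase_id or 'cell'} are not linearly "
                f"independent (volume {self.volume:g})"
            )
        self.frac_coords = self.frac_coords % 1.0

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.lattice)))

    @property
    def n_sites(self) -> int:
        return len(self.species)

    def cartesian_sites(self) -> np.ndarray:
        return self.frac_coords @ self.lattice


@dataclass
class Nanoparticle:
    """Cartesian atoms carved from a supercell, with core/shell labels."""

    positions: np.ndarray
    species: list[str]
    region: np.ndarray  # array of "core"/"shell" strings
    nominal_diameter: float  # Å
    center: np.ndarray  # Å
    phase_id: str = ""

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.center = np.asarray(self.center, dtype=float)
        self.region = np.asarray(self.region, dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def radii(self) -> np.ndarray:
        """Distance of every atom from the particle centre (Å)."""
        return np.linalg.norm(self.positions - self.center, axis=1)

    def region_mask(self, region: str) -> np.ndarray:
        if region == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if region not in ("core", "shell"):
            raise ValidationError(f"unknown region {region!r}")
        return self.region == region


def _read_number(block, tag: str) -> float:
    raw = block.find_value(tag)
    if raw is None:
        raise CifParseError(f"CIF is missing required tag {tag}")
    try:
        return gemmi.cif.as_number(raw)
    except Exception as exc:  # pragma: no cover - gemmi raises rarely here
        raise CifParseError(f"cannot parse {tag} value {raw!r}") from exc


def parse_cif(text: str, phase_id: str | None = None) -> UnitCell:
    """Parse a CIF document into a symmetry-expanded :class:`UnitCell`.

    Symmetry operators are applied to every listed site and duplicate
    images closer than :data:`MERGE_TOL` (periodic distance) are merged.
    Raises :class:`CifParseError` naming the missing tag if cell parameters
    or the atom-site loop are absent.
    """
    try:
        doc = gemmi.cif.read_string(text)
        block = doc.sole_block()
    except Exception as exc:
        raise CifParseError(f"cannot tokenise CIF document: {exc}") from exc

    params = [_read_number(block, tag) for tag in _CELL_TAGS]
    lattice = lattice_from_parameters(*params)

    labels = list(block.find_loop("_atom_site_label"))
    type_symbols = list(block.find_loop("_atom_site_type_symbol"))
    xs = list(block.find_loop("_atom_site_fract_x"))
    ys = list(block.find_loop("_atom_site_fract_y"))
    zs = list(block.find_loop("_atom_site_fract_z"))
    if not xs or not ys or not zs:
        raise CifParseError("CIF is missing the _atom_site fractional-coordinate loop")
    if not labels:
        labels = type_symbols
    if not labels:
        raise CifParseError("CIF atom_site loop has neither labels nor type symbols")

    src = type_symbols if len(type_symbols) == len(xs) else labels
    species = [normalise_species(gemmi.cif.as_string(s)) for s in src]
    frac = np.array(
        [[gemmi.cif.as_number(x), gemmi.cif.as_number(y), gemmi.cif.as_number(z)]
         for x, y, z in zip(xs, ys, zs)]
    )

    symops: list[str] = []
    for tag in _SYMOP_TAGS:
        col = list(block.find_loop(tag))
        if col:
            symops = [gemmi.cif.as_string(s).strip() for s in col]
            break
    if not symops:
        symops = ["x,y,z"]

    ops = [gemmi.Op(s) for s in symops]
    exp_species: list[str] = []
    exp_frac: list[np.ndarray] = []
    for sp, fr in zip(species, frac):
        for op in ops:
            img = np.array(op.apply_to_xyz(list(fr))) % 1.0
            if not _is_duplicate(img, exp_frac, lattice):
                exp_species.append(sp)
                exp_frac.append(img)

    return UnitCell(
        lattice=lattice,
        species=exp_species,
        frac_coords=np.array(exp_frac),
        phase_id=phase_id or block.name or "",
        symmetry_ops=symops,
    )


def _is_duplicate(frac: np.ndarray, accepted: list[np.ndarray], lattice: np.ndarray) -> bool:
    for other in accepted:
        d = frac - other
        d -= np.round(d)  # minimal image in fractional space
        if np.linalg.norm(d @ lattice) < MERGE_TOL:
            return True
    return False


def write_cif(cell: UnitCell) -> str:
    """Serialise a cell as a P1 CIF (symmetry already expanded)."""
    a, b, c = np.linalg.norm(cell.lattice, axis=1)
    al = _angle(cell.lattice[1], cell.lattice[2])
    be = _angle(cell.lattice[0], cell.lattice[2])
    ga = _angle(cell.lattice[0], cell.lattice[1])
    lines = [
        f"data_{cell.phase_id or 'cell'}",
        f"_cell_length_a {a:.8f}",
        f"_cell_length_b {b:.8f}",
        f"_cell_length_c {c:.8f}",
        f"_cell_angle_alpha {al:.8f}",
        f"_cell_angle_beta {be:.8f}",
        f"_cell_angle_gamma {ga:.8f}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "'x,y,z'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, (sp, fr) in enumerate(zip(cell.species, cell.frac_coords), start=1):
        lines.append(f"{sp}{i} {sp} {fr[0]:.8f} {fr[1]:.8f} {fr[2]:.8f}")
    return "\n".join(lines) + "\n"


def _angle(u, v) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def build_supercell(cell: UnitCell, reps: int) -> tuple[np.ndarray, list[str]]:
    """``reps`` x ``reps`` x ``reps`` translated copies of the cell contents."""
    if not isinstance(reps, (int, np.integer)) or reps <= 0:
        raise ValidationError(f"reps must be a positive integer, got {reps!r}")
    shifts = np.array(
        [(i, j, k) for i in range(reps) for j in range(reps) for k in range(reps)],
        dtype=float,
    )
    base = cell.cartesian_sites()
    translations = shifts @ cell.lattice
    positions = (translations[:, None, :] + base[None, :, :]).reshape(-1, 3)
    species = [sp for _ in range(reps**3) for sp in cell.species]
    return positions, species


def _perpendicular_widths(lattice: np.ndarray) -> np.ndarray:
    """Perpendicular width of the cell along each lattice direction (Å)."""
    vol = abs(np.linalg.det(lattice))
    widths = []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        widths.append(vol / np.linalg.norm(np.cross(lattice[j], lattice[k])))
    return np.array(widths)


def reps_for_diameter(cell: UnitCell, diameter: float, margin: float = 2.0) -> int:
    """Smallest replication count whose supercell extent covers the sphere."""
    widths = _perpendicular_widths(cell.lattice)
    return int(np.max(np.ceil((diameter + margin) / widths)))


def carve_sphere(
    cell: UnitCell,
    diameter: float,
    center_policy: str = "geometric",
    center: np.ndarray | None = None,
    shell_depth: float = DEFAULT_SHELL_DEPTH,
    reps: int | None = None,
) -> Nanoparticle:
    """Carve a spherical nanoparticle of the requested diameter (Å).

    Atoms whose distance to the centre is <= ``diameter/2`` (inclusive, with
    a 1e-8 Å tolerance) are kept.  ``center_policy``:

    - ``"geometric"`` (default): geometric centre of the supercell box;
    - ``"atom"``: the atom nearest the geometric centre;
    - an explicit ``center`` (Å, supercell frame) overrides the policy.

    The resulting particle is partitioned into core/shell with
    ``shell_depth``.  Raises :class:`EmptyParticleError` if no atom survives.
    """
    if diameter <= 0:
        raise ValidationError(f"diameter must be positive, got {diameter}")
    if reps is None:
        reps = reps_for_diameter(cell, diameter)
    positions, species = build_supercell(cell, reps)

    if center is None:
        box_center = 0.5 * reps * cell.lattice.sum(axis=0)
        if center_policy == "geometric":
            center = box_center
        elif center_policy == "atom":
            center = positions[np.argmin(np.linalg.norm(positions - box_center, axis=1))]
        else:
            raise ValidationError(f"unknown center_policy {center_policy!r}")
    center = np.asarray(center, dtype=float)

    keep = np.linalg.norm(positions - center, axis=1) <= diameter / 2 + 1e-8
    if not keep.any():
        raise EmptyParticleError(
            f"no atom of {cell.phase_id or 'cell'} lies within {diameter/2:g} Å "
            "of the requested centre"
        )
    np_ = Nanoparticle(
        positions=positions[keep],
        species=[s for s, k in zip(species, keep) if k],
        region=np.array(["shell"] * int(keep.sum()), dtype=object),
        nominal_diameter=float(diameter),
        center=center,
        phase_id=cell.phase_id,
    )
    return partition_core_shell(np_, shell_depth)


def partition_core_shell(np_: Nanoparticle, shell_depth: float = DEFAULT_SHELL_DEPTH) -> Nanoparticle:
    """Label atoms: shell iff within ``shell_depth`` of the nominal surface.

    Atom i is shell iff ``|r_i - center| >= R - shell_depth`` with
    ``R = nominal_diameter/2`` (inclusive toward shell at the boundary).
    """
    if shell_depth < 0:
        raise ValidationError(f"shell_depth must be >= 0, got {shell_depth}")
    if np_.n_atoms < 1:
        raise ValidationError("cannot partition an empty particle")
    radius = np_.nominal_diameter / 2.0
    shell = np_.radii() >= radius - shell_depth - 1e-12
    region = np.where(shell, "shell", "core").astype(object)
    return replace(np_, region=region)


def to_xyz(np_: Nanoparticle) -> str:
    """Extended XYZ text: element, x, y, z, region; metadata in the comment."""
    lines = [
        str(np_.n_atoms),
        f"phase={np_.phase_id} diameter_ang={np_.nominal_diameter:g} "
        "columns=element,x,y,z,region",
    ]
    for sp, pos, reg in zip(np_.species, np_.positions, np_.region):
        lines.append(f"{sp} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} {reg}")
    return "\n".join(lines) + "\n"
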