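"""Backbone-only PDB structures, the searchable structure database, and
rigid-body superposition.

Only the four backbone heavy atoms (N, CA, C, O) are retained: the motif
search operates on full-backbone RMSD and side chains are modelled
implicitly through rotamer libraries elsewhere in the package.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}

ONE_TO_THREE = {v: k for k, v in list(THREE_TO_ONE.items())[:20]}


class EmptyStructureError(ValueError):
    """Raised when no complete backbone residue survives parsing."""


class EmptyDatabaseError(ValueError):
    """Raised when every manifest chain is filtered out."""


@dataclass(frozen=True)
class Residue:
    """One residue: amino-acid identity plus the 4 backbone atoms.

    ``coords`` rows are N, CA, C, O (Angstrom). ``author_number`` keeps the
    original PDB residue number + insertion code for reporting only.
    """

    aa: str
    coords: np.ndarray  # (4, 3)
    author_number: str = ""

    def __post_init__(self) -> None:
        if self.aa not in AA_INDEX:
            raise ValueError(f"non-standard amino acid {self.aa!r}")
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (4, 3) or not np.all(np.isfinite(c)):
            raise ValueError("backbone coordinates must be a finite (4,3) array")
        object.__setattr__(self, "coords", c)


@dataclass
class BackboneStructure:
    """An ordered single-chain backbone. Internal indices are 0-based."""

    chain_id: str
    residues: list[Residue]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self, indices: Iterable[int] | None = None) -> np.ndarray:
        """Backbone coordinates, 4 atoms per residue, shape (4*k, 3)."""
        if indices is None:
            indices = range(len(self.residues))
        return np.concatenate([self.residues[i].coords for i in indices], axis=0)

    def ca_coords(self) -> np.ndarray:
        return np.stack([r.coords[1] for r in self.residues], axis=0)


@dataclass
class AminoAcidDistribution:
    """Background amino-acid frequencies P0 over the 20 standard residues."""

    freq: np.ndarray  # (20,)

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (20,):
            raise ValueError("need exactly 20 frequencies")
        if np.any(f <= 0):
            raise ValueError("frequencies must be strictly positive (pseudocounted)")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        self.freq = f

    def __getitem__(self, aa: str) -> float:
        return float(self.freq[AA_INDEX[aa]])

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 1.0) -> "AminoAcidDistribution":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum())

    @classmethod
    def uniform(cls) -> "AminoAcidDistribution":
        return cls(np.full(20, 1.0 / 20.0))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dict(zip(AMINO_ACIDS, self.freq.tolist())), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AminoAcidDistribution":
        d = json.loads(Path(path).read_text())
        return cls(np.array([d[a] for a in AMINO_ACIDS], dtype=float))


@dataclass
class StructureDatabase:
    """The searchable collection of backbone chains.

    ``background`` is the overall amino-acid distribution of the retained
    residues and doubles as the model's background bias P0.
    """

    entries: list[BackboneStructure]
    background: AminoAcidDistribution
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.source_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate source_id in database")
        if not self.sequences:
            self.sequences = {e.source_id: e.sequence for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, source_id: str) -> BackboneStructure:
        for e in self.entries:
            if e.source_id == source_id:
                return e
        raise KeyError(source_id)

    def subsample(self, fraction: float, rng: np.random.Generator) -> "StructureDatabase":
        """Random chain subsample of floor(fraction * n) chains, background recomputed."""
        n = int(np.floor(fraction * len(self.entries)))
        idx = rng.choice(len(self.entries), size=n, replace=False)
        entries = [self.entries[i] for i in sorted(idx)]
        counts = np.zeros(20)
        for e in entries:
            for r in e.residues:
                counts[AA_INDEX[r.aa]] += 1
        return StructureDatabase(entries, AminoAcidDistribution.from_counts(counts))


def _parse_atom_line(line: str):
    name = line[12:16].strip()
    altloc = line[16]
    resname = line[17:20].strip()
    chain = line[21]
    resseq = line[22:27].strip()  # number + insertion code
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    try:
        occ = float(line[54:60])
    except (ValueError, IndexError):
        occ = 1.0
    return name, altloc, resname, chain, resseq, (x, y, z), occ


def read_pdb_backbone(path: str | Path, chain: str) -> BackboneStructure:
    """Parse one chain of a PDB file into a backbone-only structure.

    Residues missing any of N/CA/C/O are dropped with a warning; alternate
    locations resolve to the highest occupancy (ties: altloc letter order);
    recognised modified residues map to their parent amino acid, anything
    else is dropped.
    """
    path = Path(path)
    seen_chains: set[str] = set()
    # residue order of first appearance; per residue: atom -> (occ, altloc, xyz)
    order: list[str] = []
    residues: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            name, altloc, resname, ch, resseq, xyz, occ = _parse_atom_line(line)
            seen_chains.add(ch)
            if ch != chain or name not in BACKBONE_ATOMS:
                continue
            aa = THREE_TO_ONE.get(resname)
            if aa is None:
                continue
            key = resseq
            rec = residues.setdefault(key, {"aa": aa, "atoms": {}})
            if key not in order:
                order.append(key)
            prev = rec["atoms"].get(name)
            cand = (occ, altloc, xyz)
            if prev is None or (cand[0], _alt_rank(cand[1])) > (prev[0], _alt_rank(prev[1])):
                rec["atoms"][name] = cand

    if chain not in seen_chains:
        raise KeyError(f"chain {chain!r} not present in {path}")

    out: list[Residue] = []
    for key in order:
        rec = residues[key]
        atoms = rec["atoms"]
        if any(a not in atoms for a in BACKBONE_ATOMS):
            logger.warning("dropping residue %s (incomplete backbone) in %s:%s", key, path, chain)
            continue
        coords = np.array([atoms[a][2] for a in BACKBONE_ATOMS], dtype=float)
        out.append(Residue(rec["aa"], coords, author_number=key))
    if not out:
        raise EmptyStructureError(f"no complete backbone residues in {path}:{chain}")
    return BackboneStructure(chain_id=chain, residues=out, source_id=f"{path.stem}_{chain}")


def _alt_rank(altloc: str) -> int:
    # higher is preferred; blank beats lettered, 'A' beats 'B' etc.
    if altloc in (" ", ""):
        return 1000
    return 255 - ord(altloc)


def write_pdb_backbone(structure: BackboneStructure, path: str | Path) -> None:
    """Write backbone ATOM records (one chain) in PDB format."""
    lines = []
    serial = 1
    for i, res in enumerate(structure.residues):
        resname = ONE_TO_THREE[res.aa]
        num = res.author_number or str(i + 1)
        # split insertion code if present
        icode = " "
        numeric = num
        if num and not num[-1].isdigit():
            icode = num[-1]
            numeric = num[:-1]
        for atom, xyz in zip(BACKBONE_ATOMS, res.coords):
            lines.append(
                f"ATOM  {serial:5d} {atom:^4s}{resname:>4s} {structure.chain_id}"
                f"{int(numeric):4d}{icode}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a TSV manifest: source_id, path, chain, [extra metadata columns]."""
    rows = []
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sid, p, chain = parts[0], parts[1], parts[2]
            p = str((base / p)) if not Path(p).is_absolute() else p
            rows.append((sid, p, chain))
    return rows


def build_database(
    manifest: Sequence[tuple[str, str, str]] | str | Path,
    min_length: int = 30,
) -> StructureDatabase:
    """Load manifest chains, drop peptides shorter than ``min_length``, and
    compute the pseudocounted background amino-acid distribution.

    ``manifest`` is either a path to a TSV (source_id, path, chain, ...) or
    an in-memory list of (source_id, path, chain) tuples.
    """
    if isinstance(manifest, (str, Path)):
        manifest = read_manifest(manifest)
    if not manifest:
        raise ValueError("manifest is empty")
    entries: list[BackboneStructure] = []
    counts = np.zeros(20)
    for sid, p, chain in manifest:
        s = read_pdb_backbone(p, chain)
        s.source_id = sid
        if len(s) < min_length:
            logger.info("excluding %s: %d residues < min_length %d", sid, len(s), min_length)
            continue
        entries.append(s)
        for r in s.residues:
            counts[AA_INDEX[r.aa]] += 1
    if not entries:
        raise EmptyDatabaseError("all chains excluded by the length filter")
    return StructureDatabase(entries, AminoAcidDistribution.from_counts(counts))


def database_from_structures(structures: Sequence[BackboneStructure], min_length: int = 0) -> StructureDatabase:
    """Build a database directly from in-memory structures (fixtures, tests)."""
    entries = [s for s in structures if len(s) >= min_length]
    if not entries:
        raise EmptyDatabaseError("no structures retained")
    counts = np.zeros(20)
    for s in entries:
        for r in s.residues:
            counts[AA_INDEX[r.aa]] += 1
    return StructureDatabase(list(entries), AminoAcidDistribution.from_counts(counts))


def superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between two equal-length point sets over all rigid-body
    transforms (closed-form least squares, proper rotations only)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("point sets must be matching (n>=3, 3) arrays")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    # Kabsch: SSD after optimal rotation = sum|a|^2 + sum|b|^2 - 2*sum(d_i * sv_i)
    h = ac.T @ bc
    sv = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    if det < 0:
        sv = sv.copy()
        sv[-1] = -sv[-1]
    ssd = (ac * ac).sum() + (bc * bc).sum() - 2.0 * sv.sum()
    return float(np.sqrt(max(ssd, 0.0) / a.shape[0]))


def superpose_transform(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal (rotation, translation) mapping ``mobile`` onto ``target``."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans
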