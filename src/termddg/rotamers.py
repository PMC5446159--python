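"""Simplified side-chain rotamer library.

Side chains are built from idealized internal coordinates (bond lengths,
angles, and chi torsions) with rotamers enumerated over chi1/chi2 in
{-60, 60, 180} degrees and any further torsions fixed trans. Coordinates
are expressed in a canonical N-CA-C backbone frame so a rotamer can be
rigidly mapped onto any residue. This is deliberately a coarse,
backbone-independent stand-in for a statistical rotamer library: the
occupancy metrics built on top of it (contact degree, freedom) only need
relative geometric occupancy, not rotamer thermodynamics.

A library in the same JSON schema (per amino acid: list of rotamers with
atom names, coordinates in the canonical frame, and probabilities) can be
supplied in its place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from termddg.structure_io import AMINO_ACIDS, superpose_transform

# Canonical backbone frame: CA at origin, C on +x, N in the xy plane.
_N_CA, _CA_C = 1.458, 1.525
_N_CA_C = np.deg2rad(111.2)
CANONICAL_BACKBONE = np.array(
    [
        [_N_CA * np.cos(_N_CA_C), _N_CA * np.sin(_N_CA_C), 0.0],  # N
        [0.0, 0.0, 0.0],  # CA
        [_CA_C, 0.0, 0.0],  # C
    ]
)

# Torsion specs: ("chi", k, offset_deg) -> chi_k + offset; ("fix", deg) -> fixed.
# Atom rows: (name, (ref_a, ref_b, ref_c), bond, angle_deg, torsion_spec)
# where the torsion is over ref_a - ref_b - ref_c - atom.
_CB = ("CB", ("N", "C", "CA"), 1.52, 110.1, ("fix", 122.55))

_TOPOLOGY: dict[str, list] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ("OG", ("N", "CA", "CB"), 1.42, 110.5, ("chi", 1, 0.0))],
    "C": [_CB, ("SG", ("N", "CA", "CB"), 1.81, 113.8, ("chi", 1, 0.0))],
    "T": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.43, 109.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.53, 111.0, ("chi", 1, 120.0)),
    ],
    "V": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.53, 111.0, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.53, 111.0, ("chi", 1, 122.0)),
    ],
    "L": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.53, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.53, 110.7, ("chi", 2, 122.0)),
    ],
    "I": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, 122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.53, 113.8, ("chi", 2, 0.0)),
    ],
    "M": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.81, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, ("fix", 180.0)),
    ],
    "P": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 104.5, ("fix", 28.0)),
        ("CD", ("CA", "CB", "CG"), 1.51, 106.1, ("fix", -35.0)),
    ],
    "F": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, ("fix", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fix", 0.0)),
    ],
    "W": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.9, ("chi", 2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, ("fix", 180.0)),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, ("fix", 0.0)),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, ("fix", 180.0)),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, ("fix", 180.0)),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, ("fix", 0.0)),
    ],
    "H": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.1, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.33, 109.2, ("fix", 180.0)),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, ("fix", 180.0)),
    ],
    "D": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 113.1, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 180.0)),
    ],
    "N": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 112.7, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.5, ("chi", 2, 180.0)),
    ],
    "E": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.2, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, ("fix", 180.0)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, ("fix", 0.0)),
    ],
    "Q": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.2, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, ("fix", 180.0)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, ("fix", 0.0)),
    ],
    "K": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, ("fix", 180.0)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, ("fix", 180.0)),
    ],
    "R": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, ("fix", 180.0)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, ("fix", 180.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, ("fix", 0.0)),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, ("fix", 180.0)),
    ],
    "Y": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, ("fix", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fix", 0.0)),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, ("fix", 180.0)),
    ],
}

# number of sampled chi torsions per amino acid (chi1/chi2 at most)
_N_CHI = {
    "G": 0, "A": 0, "P": 0, "S": 1, "C": 1, "T": 1, "V": 1,
    "L": 2, "I": 2, "M": 2, "F": 2, "W": 2, "H": 2, "D": 2,
    "N": 2, "E": 2, "Q": 2, "K": 2, "R": 2, "Y": 2,
}

_CHI_VALUES = (-60.0, 60.0, 180.0)


def place_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D from reference atoms A, B, C."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@dataclass(frozen=True)
class Rotamer:
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) in the canonical N-CA-C frame
    prob: float


class RotamerLibrary:
    """Per-amino-acid rotamers with probabilities, in a canonical frame."""

    def __init__(self, rotamers: dict[str, list[Rotamer]]):
        for aa in AMINO_ACIDS:
            if aa not in rotamers:
                raise ValueError(f"library missing amino acid {aa}")
            total = sum(r.prob for r in rotamers[aa])
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"rotamer probabilities for {aa} sum to {total}, not 1")
        self.rotamers = rotamers
        self.max_reach = self._max_reach()

    def _max_reach(self) -> float:
        """Largest side-chain-atom distance from CA over the whole library."""
        reach = 0.0
        for rots in self.rotamers.values():
            for r in rots:
                if len(r.coords):
                    reach = max(reach, float(np.linalg.norm(r.coords, axis=1).max()))
        return reach

    def __getitem__(self, aa: str) -> list[Rotamer]:
        return self.rotamers[aa]

    def to_json(self, path: str | Path) -> None:
        out = {
            aa: [
                {
                    "atoms": list(r.atom_names),
                    "coords": r.coords.tolist(),
                    "prob": r.prob,
                }
                for r in rots
            ]
            for aa, rots in self.rotamers.items()
        }
        Path(path).write_text(json.dumps(out))

    @classmethod
    def from_json(cls, path: str | Path) -> "RotamerLibrary":
        raw = json.loads(Path(path).read_text())
        rotamers = {
            aa: [
                Rotamer(tuple(r["atoms"]), np.array(r["coords"], dtype=float).reshape(-1, 3), float(r["prob"]))
                for r in rots
            ]
            for aa, rots in raw.items()
        }
        return cls(rotamers)


def _build_rotamer(aa: str, chis: tuple[float, ...]) -> Rotamer:
    pos = {"N": CANONICAL_BACKBONE[0], "CA": CANONICAL_BACKBONE[1], "C": CANONICAL_BACKBONE[2]}
    names, coords = [], []
    for name, refs, bond, angle, tspec in _TOPOLOGY[aa]:
        if tspec[0] == "fix":
            torsion = tspec[1]
        else:
            _, k, off = tspec
            torsion = (chis[k - 1] if k - 1 < len(chis) else 180.0) + off
        xyz = place_internal(pos[refs[0]], pos[refs[1]], pos[refs[2]], bond, angle, torsion)
        pos[name] = xyz
        names.append(name)
        coords.append(xyz)
    arr = np.array(coords, dtype=float).reshape(-1, 3)
    return Rotamer(tuple(names), arr, 0.0)


def default_library() -> RotamerLibrary:
    """The packaged idealized chi-rotamer library (uniform probabilities)."""
    rotamers: dict[str, list[Rotamer]] = {}
    for aa in AMINO_ACIDS:
        nchi = _N_CHI[aa]
        combos = list(product(_CHI_VALUES, repeat=nchi)) if nchi else [()]
        rots = [_build_rotamer(aa, c) for c in combos]
        p = 1.0 / len(rots)
        rotamers[aa] = [Rotamer(r.atom_names, r.coords, p) for r in rots]
    return RotamerLibrary(rotamers)


def transform_to_residue(coords: np.ndarray, backbone_nca_c: np.ndarray) -> np.ndarray:
    """Map canonical-frame coordinates onto a residue's actual N/CA/C atoms."""
    rot, trans = superpose_transform(CANONICAL_BACKBONE, backbone_nca_c)
    if len(coords) == 0:
        return coords.reshape(0, 3)
    return coords @ rot.T + trans
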