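"""Rotamer-based contact degree, the freedom burial metric, freedom-binned
amino-acid propensities, and the contact-degree-binned statistical contact
potential.

Contact degree c(i, j) is the probability-weighted fraction of mutually
non-clashing rotamer pairs at two positions whose heavy atoms approach
within 3 A, with weights Pr(a) Pr(b) p(r_i) p(r_j) combining background
amino-acid frequencies and rotamer probabilities. Freedom is the weighted
fraction of rotamers a position's backbone environment accommodates
without clashes — a sequence-independent burial measure used to compute
the expected amino-acid pair counts behind the contact potential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from termddg.rotamers import RotamerLibrary, default_library, transform_to_residue
from termddg.structure_io import (
    AA_INDEX,
    AMINO_ACIDS,
    AminoAcidDistribution,
    BackboneStructure,
    StructureDatabase,
)

CONTACT_THRESHOLD = 0.02
CLASH_CUTOFF = 2.5  # heavy-atom distance below which a rotamer clashes with backbone
INTERACTION_CUTOFF = 3.0  # heavy-atom pair distance defining I_ij = 1

POTENTIAL_BINS = ((0.02, 0.05), (0.05, 0.1), (0.1, 0.2), (0.2, 0.5), (0.5, 1.0 + 1e-12))
N_FREEDOM_BINS = 70


class NoContactsError(ValueError):
    """Raised when a database yields no contacting pairs at all."""


@dataclass
class PlacedRotamer:
    aa: str
    weight: float  # Pr(a) * p(r)
    coords: np.ndarray  # (n_atoms, 3), possibly empty for Gly


class ContactEngine:
    """Caches placed, clash-pruned rotamers per position of one structure.

    All per-position quantities (contact degree, freedom, contact sets) go
    through this class; the module-level functions are thin wrappers that
    construct a throwaway engine.
    """

    def __init__(
        self,
        structure: BackboneStructure,
        lib: RotamerLibrary | None = None,
        background: AminoAcidDistribution | None = None,
        clash_cutoff: float = CLASH_CUTOFF,
        interaction_cutoff: float = INTERACTION_CUTOFF,
        distance_cap: float | None = None,
    ):
        self.structure = structure
        self.lib = lib if lib is not None else default_library()
        self.background = background if background is not None else AminoAcidDistribution.uniform()
        self.clash_cutoff = clash_cutoff
        self.interaction_cutoff = interaction_cutoff
        # beyond this CA-CA distance no heavy-atom pair can approach within
        # the interaction cutoff, for the library in use (provable cap)
        if distance_cap is None:
            distance_cap = 2.0 * self.lib.max_reach + interaction_cutoff
        self.distance_cap = distance_cap
        self._backbone = structure.coords()  # (4L, 3)
        self._placed: dict[int, list[PlacedRotamer]] = {}
        self._stacks: dict[int, tuple] = {}

    # -- rotamer placement -------------------------------------------------

    def _backbone_mask(self, i: int) -> np.ndarray:
        """Backbone atoms of residues other than i and its sequence neighbors."""
        L = len(self.structure)
        keep = np.ones(4 * L, dtype=bool)
        for k in range(max(0, i - 1), min(L, i + 2)):
            keep[4 * k : 4 * k + 4] = False
        return keep

    def place_rotamer(self, i: int, aa: str, rotamer) -> np.ndarray | None:
        """Rigidly map a rotamer onto residue i; None signals a backbone clash."""
        res = self.structure.residues[i]
        coords = transform_to_residue(rotamer.coords, res.coords[:3])
        if len(coords) == 0:
            return coords
        other = self._backbone[self._backbone_mask(i)]
        if len(other) and cdist(coords, other).min() < self.clash_cutoff:
            return None
        return coords

    def placed_rotamers(self, i: int) -> list[PlacedRotamer]:
        """All clash-surviving rotamers at i, weighted by Pr(a) p(r)."""
        if i not in self._placed:
            out = []
            for aa in AMINO_ACIDS:
                pr_a = self.background[aa]
                for rot in self.lib[aa]:
                    coords = self.place_rotamer(i, aa, rot)
                    if coords is not None:
                        out.append(PlacedRotamer(aa, pr_a * rot.prob, coords))
            self._placed[i] = out
        return self._placed[i]

    def _stacked(self, i: int):
        """Surviving rotamers at i as (atoms, atom->rotamer index, weights)."""
        if i not in self._stacks:
            placed = self.placed_rotamers(i)
            weights = np.array([p.weight for p in placed], dtype=float)
            if placed:
                atoms = np.concatenate(
                    [p.coords for p in placed if len(p.coords)] or [np.empty((0, 3))], axis=0
                )
                rot_idx = np.concatenate(
                    [np.full(len(p.coords), k) for k, p in enumerate(placed) if len(p.coords)]
                    or [np.empty(0, dtype=int)]
                ).astype(int)
            else:
                atoms = np.empty((0, 3))
                rot_idx = np.empty(0, dtype=int)
            self._stacks[i] = (atoms, rot_idx, weights)
        return self._stacks[i]

    # -- metrics -----------------------------------------------------------

    def freedom(self, i: int) -> float:
        """Weighted fraction of all rotamers accommodated by the backbone."""
        total = sum(
            self.background[aa] * rot.prob for aa in AMINO_ACIDS for rot in self.lib[aa]
        )
        kept = sum(p.weight for p in self.placed_rotamers(i))
        return float(kept / total)

    def contact_degree(self, i: int, j: int) -> float:
        if i == j or abs(i - j) < 2:
            raise ValueError("contact degree requires non-adjacent positions")
        ca_i = self.structure.residues[i].coords[1]
        ca_j = self.structure.residues[j].coords[1]
        if np.linalg.norm(ca_i - ca_j) > self.distance_cap:
            return 0.0
        atoms_i, rot_i, w_i = self._stacked(i)
        atoms_j, rot_j, w_j = self._stacked(j)
        denom = w_i.sum() * w_j.sum()
        if denom == 0.0:
            return 0.0
        if len(atoms_i) == 0 or len(atoms_j) == 0:
            return 0.0
        close = cdist(atoms_i, atoms_j) < self.interaction_cutoff
        pair_hit = np.zeros((len(w_i), len(w_j)), dtype=bool)
        hit_a, hit_b = np.nonzero(close)
        pair_hit[rot_i[hit_a], rot_j[hit_b]] = True
        num = float(w_i @ pair_hit @ w_j)
        return float(num / denom)

    def contact_set(self, i: int, threshold: float = CONTACT_THRESHOLD) -> list[int]:
        """Positions j with c(i, j) strictly above threshold, by descending degree."""
        if not 0 < threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        degrees = []
        for j in range(len(self.structure)):
            if abs(j - i) < 2:
                continue
            c = self.contact_degree(i, j)
            if c > threshold:
                degrees.append((c, j))
        degrees.sort(key=lambda t: (-t[0], t[1]))
        return [j for _, j in degrees]

    def all_contacts(self, threshold: float = CONTACT_THRESHOLD) -> list[tuple[int, int, float]]:
        """All (i, j, degree) with i < j - 1 and degree above threshold."""
        out = []
        L = len(self.structure)
        for i in range(L):
            for j in range(i + 2, L):
                c = self.contact_degree(i, j)
                if c > threshold:
                    out.append((i, j, c))
        return out


# -- module-level wrappers -------------------------------------------------

def place_rotamer(structure, i, aa, rotamer, lib=None, clash_cutoff=CLASH_CUTOFF):
    return ContactEngine(structure, lib, clash_cutoff=clash_cutoff).place_rotamer(i, aa, rotamer)


def contact_degree(structure, i, j, lib=None, background=None):
    return ContactEngine(structure, lib, background).contact_degree(i, j)


def contact_set(structure, i, lib=None, background=None, threshold=CONTACT_THRESHOLD):
    return ContactEngine(structure, lib, background).contact_set(i, threshold)


def freedom(structure, i, lib=None, background=None):
    return ContactEngine(structure, lib, background).freedom(i)


# -- freedom propensities and the contact potential ------------------------

@dataclass
class FreedomTable:
    """P(a | freedom bin) over equally spaced freedom bins on [0, 1]."""

    propensity: np.ndarray  # (20, n_bins), columns sum to 1
    n_bins: int = N_FREEDOM_BINS

    def bin_of(self, f: float) -> int:
        return min(int(f * self.n_bins), self.n_bins - 1)

    def column(self, f: float) -> np.ndarray:
        return self.propensity[:, self.bin_of(f)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"n_bins": self.n_bins, "propensity": self.propensity.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "FreedomTable":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["propensity"], dtype=float), d["n_bins"])


def freedom_propensities(
    db: StructureDatabase,
    lib: RotamerLibrary | None = None,
    n_bins: int = N_FREEDOM_BINS,
    pseudocount: float = 1.0,
) -> FreedomTable:
    """Amino-acid propensities conditioned on the freedom (burial) bin.

    Empty bins fall back to the database background distribution.
    """
    if len(db) == 0:
        raise ValueError("database is empty")
    lib = lib if lib is not None else default_library()
    counts = np.zeros((20, n_bins))
    for entry in db.entries:
        engine = ContactEngine(entry, lib, db.background)
        for i, res in enumerate(entry.residues):
            f = engine.freedom(i)
            b = min(int(f * n_bins), n_bins - 1)
            counts[AA_INDEX[res.aa], b] += 1
    prop = np.empty_like(counts)
    for b in range(n_bins):
        if counts[:, b].sum() == 0:
            prop[:, b] = db.background.freq
        else:
            col = counts[:, b] + pseudocount
            prop[:, b] = col / col.sum()
    return FreedomTable(prop, n_bins)


@dataclass
class ContactPotential:
    """20x20 symmetric statistical potential per contact-degree bin."""

    j_hat: np.ndarray  # (n_bins, 20, 20)
    bins: tuple = POTENTIAL_BINS
    n_obs: np.ndarray | None = None
    n_exp: np.ndarray | None = None

    def bin_of(self, degree: float) -> int:
        for b, (lo, hi) in enumerate(self.bins):
            if lo <= degree < hi:
                return b
        # degrees above the threshold but outside all bins clamp to the ends
        return 0 if degree < self.bins[0][0] else len(self.bins) - 1

    def matrix(self, degree: float) -> np.ndarray:
        return self.j_hat[self.bin_of(degree)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"bins": [list(b) for b in self.bins], "j_hat": self.j_hat.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ContactPotential":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["j_hat"], dtype=float), tuple(tuple(b) for b in d["bins"]))

    @classmethod
    def zeros(cls) -> "ContactPotential":
        return cls(np.zeros((len(POTENTIAL_BINS), 20, 20)))


def expected_pair_counts(pair_props: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Expected amino-acid pair counts given per-contact freedom propensities.

    For each contact with per-position propensity columns (Pk, Pl),
    N_exp(a, b) = [Pk(a) Pl(b) + Pk(b) Pl(a)] / (1 + I[a = b]); summing the
    result over unordered pairs returns the number of contacts.
    """
    n_exp = np.zeros((20, 20))
    for pk, pl in pair_props:
        n_exp += np.outer(pk, pl) + np.outer(pl, pk)
    n_exp /= 1.0 + np.eye(20)
    return n_exp


def contact_potential(
    db: StructureDatabase,
    lib: RotamerLibrary | None = None,
    ft: FreedomTable | None = None,
    threshold: float = CONTACT_THRESHOLD,
    pseudocount: float = 1.0,
) -> ContactPotential:
    """Contact-degree-binned statistical potential J_hat = -ln(N_obs/N_exp).

    Collects every contacting pair (degree above threshold) in the database,
    splits them across the five contact-degree bins, tallies observed pair
    counts and freedom-propensity-based expected counts, and applies +1
    pseudocounts so every cell is finite.
    """
    lib = lib if lib is not None else default_library()
    if ft is None:
        ft = freedom_propensities(db, lib)
    nb = len(POTENTIAL_BINS)
    n_obs = np.zeros((nb, 20, 20))
    pair_props: list[list] = [[] for _ in range(nb)]
    total = 0
    for entry in db.entries:
        engine = ContactEngine(entry, lib, db.background)
        freedoms = {}
        for i, j, deg in engine.all_contacts(threshold):
            b = None
            for bi, (lo, hi) in enumerate(POTENTIAL_BINS):
                if lo <= deg < hi:
                    b = bi
                    break
            if b is None:
                continue
            a_i = AA_INDEX[entry.residues[i].aa]
            a_j = AA_INDEX[entry.residues[j].aa]
            n_obs[b, a_i, a_j] += 1
            if a_i != a_j:
                n_obs[b, a_j, a_i] += 1
            for k in (i, j):
                if k not in freedoms:
                    freedoms[k] = engine.freedom(k)
            pair_props[b].append((ft.column(freedoms[i]), ft.column(freedoms[j])))
            total += 1
    if total == 0:
        raise NoContactsError("no contacting pairs found in the database")
    j_hat = np.empty((nb, 20, 20))
    n_exp = np.zeros((nb, 20, 20))
    for b in range(nb):
        n_exp[b] = expected_pair_counts(pair_props[b]) if pair_props[b] else 0.0
        j_hat[b] = -np.log((n_obs[b] + pseudocount) / (n_exp[b] + pseudocount))
    return ContactPotential(j_hat, POTENTIAL_BINS, n_obs=n_obs, n_exp=n_exp)
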