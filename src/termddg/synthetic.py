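"""Programmatic generation of every input the package needs for testing:
toy backbone databases with planted motif copies, Boltzmann-sampled match
ensembles from known energy parameters, and synthetic deep-sequencing
count tables built by inverting the fitness-to-ddG transformation.

Chains are built with ideal bond geometry (Engh/Huber-like constants)
from standard phi/psi values — helix (-60, -45), strand (-120, 120) —
with small seeded noise, so they look like idealized protein backbones
but carry none of the packing, loop irregularity, or sequence-structure
coupling of real chains (beyond what is explicitly planted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from termddg.ep_model import EPSet
from termddg.rotamers import place_internal
from termddg.structure_io import (
    AA_INDEX,
    AMINO_ACIDS,
    AminoAcidDistribution,
    BackboneStructure,
    Residue,
    StructureDatabase,
    database_from_structures,
    write_pdb_backbone,
)
from termddg.term_engine import Match, MatchEnsemble, Term

# ideal backbone geometry (bond lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

PHI_PSI = {"helix": (-60.0, -45.0), "strand": (-120.0, 120.0), "pp2": (-75.0, 145.0)}


def build_backbone_chain(
    phi_psi: np.ndarray,
    sequence: str,
    chain_id: str = "A",
    source_id: str = "synth",
) -> BackboneStructure:
    """Ideal-geometry backbone from per-residue (phi, psi) torsions (deg)."""
    L = len(sequence)
    phi_psi = np.asarray(phi_psi, dtype=float).reshape(L, 2)
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c = ca + _B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    atoms = [[n, ca, c]]
    for i in range(1, L):
        n_prev, ca_prev, c_prev = atoms[-1]
        psi_prev = phi_psi[i - 1, 1]
        n_i = place_internal(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = place_internal(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = place_internal(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_psi[i, 0])
        atoms.append([n_i, ca_i, c_i])
    residues = []
    for i in range(L):
        n_i, ca_i, c_i = atoms[i]
        # carbonyl O anti to the next amide nitrogen (psi + 180)
        o_i = place_internal(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, phi_psi[i, 1] + 180.0)
        coords = np.stack([n_i, ca_i, c_i, o_i])
        residues.append(Residue(sequence[i], coords, author_number=str(i + 1)))
    return BackboneStructure(chain_id=chain_id, residues=residues, source_id=source_id)


def _mixed_phi_psi(length: int, rng: np.random.Generator, noise_deg: float = 6.0) -> np.ndarray:
    """Blocks of helix and strand with seeded noise."""
    out = np.empty((length, 2))
    i = 0
    while i < length:
        style = rng.choice(["helix", "strand"])
        block = int(rng.integers(6, 14))
        pp = PHI_PSI[style]
        for k in range(min(block, length - i)):
            out[i + k] = pp + rng.normal(0.0, noise_deg, size=2)
        i += block
    return out


def random_sequence(length: int, rng: np.random.Generator, dist: AminoAcidDistribution | None = None) -> str:
    p = dist.freq if dist is not None else np.full(20, 0.05)
    idx = rng.choice(20, size=length, p=p)
    return "".join(AMINO_ACIDS[i] for i in idx)


@dataclass
class MotifTemplate:
    """A rigid multi-segment backbone motif with a designated seed residue."""

    segments: list[np.ndarray]  # each (n_res, 4, 3)
    seed_segment: int = 0
    seed_offset: int = 0  # residue offset of the seed within its segment

    @property
    def segment_lengths(self) -> list[int]:
        return [s.shape[0] for s in self.segments]

    def all_coords(self) -> np.ndarray:
        return np.concatenate([s.reshape(-1, 3) for s in self.segments], axis=0)


IRREGULAR_PHI_PSI = np.array(
    [(-100.0, 60.0), (55.0, 45.0), (-140.0, 80.0), (-70.0, 150.0), (65.0, -60.0),
     (-110.0, 20.0), (50.0, 80.0), (-90.0, 130.0)]
)


def make_motif_template(
    n_res: int = 5,
    n_segments: int = 1,
    seed_offset: int | None = None,
    rng: np.random.Generator | None = None,
) -> MotifTemplate:
    """A geometrically distinctive motif built from irregular torsions.

    Multi-segment templates are cut from one continuous irregular chain,
    so the segments carry a fixed relative orientation.
    """
    rng = rng or np.random.default_rng(0)
    total = n_res * n_segments + 4 * (n_segments - 1) + 2
    pp = IRREGULAR_PHI_PSI[np.arange(total) % len(IRREGULAR_PHI_PSI)] + rng.normal(0, 2.0, (total, 2))
    chain = build_backbone_chain(pp, "A" * total)
    segments = []
    start = 1
    for _ in range(n_segments):
        seg = np.stack([chain.residues[p].coords for p in range(start, start + n_res)])
        segments.append(seg)
        start += n_res + 4
    if seed_offset is None:
        seed_offset = n_res // 2
    return MotifTemplate(segments, seed_segment=0, seed_offset=seed_offset)


@dataclass
class Planted:
    template: MotifTemplate
    copies: int
    jitter: float = 0.0  # per-coordinate Gaussian sd, A
    # "background" or ("boltzmann", truth EPSet over no contacts, P0)
    sequence_model: object = "background"


@dataclass
class FixtureSpec:
    seed: int
    n_chains: int = 20
    chain_length: int = 60
    planted: list[Planted] = field(default_factory=list)
    noise_deg: float = 6.0


@dataclass
class Placement:
    source_id: str
    windows: tuple[tuple[int, int], ...]  # inclusive residue windows per segment
    seed_position: int
    seed_aa: str


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-20, 20, size=3)


def _sample_seed_aa(truth: EPSet, P0: AminoAcidDistribution, rng: np.random.Generator,
                    ctx: dict[int, int] | None = None) -> str:
    e = truth.sEP.copy()
    if ctx:
        for j, yi in ctx.items():
            e = e + truth.pEP[j][:, yi]
    logit = -e + np.log(P0.freq)
    logit -= logit.max()
    p = np.exp(logit)
    p /= p.sum()
    return AMINO_ACIDS[rng.choice(20, p=p)]


def make_backbone_db(
    spec: FixtureSpec,
    out_dir: str | Path | None = None,
) -> tuple[StructureDatabase, list[Placement]]:
    """Generate the fixture database and return it with the placement log.

    Chains are ideal helix/strand composites; each planted motif copy
    overwrites randomly chosen non-overlapping windows of a random chain
    with a rigidly transformed, jittered copy of the template. Optionally
    writes PDB files plus a TSV manifest to ``out_dir``.
    """
    rng = np.random.default_rng(spec.seed)
    chains = []
    for c in range(spec.n_chains):
        sid = f"synth{c:03d}_A"
        pp = _mixed_phi_psi(spec.chain_length, rng, spec.noise_deg)
        seq = random_sequence(spec.chain_length, rng)
        chains.append(build_backbone_chain(pp, seq, "A", sid))

    occupied: dict[int, list[tuple[int, int]]] = {c: [] for c in range(spec.n_chains)}
    log: list[Placement] = []
    for planted in spec.planted:
        tmpl = planted.template
        lengths = tmpl.segment_lengths
        for _ in range(planted.copies):
            for _attempt in range(200):
                c = int(rng.integers(spec.n_chains))
                windows = []
                ok = True
                taken = list(occupied[c])
                for n_res in lengths:
                    w = int(rng.integers(1, spec.chain_length - n_res - 1))
                    span = (w, w + n_res - 1)
                    if any(span[0] <= b + 1 and a - 1 <= span[1] for a, b in taken):
                        ok = False
                        break
                    taken.append(span)
                    windows.append(span)
                if ok:
                    break
            else:
                raise RuntimeError("could not place motif copy; reduce copies or grow chains")
            occupied[c].extend(windows)
            rot, trans = _random_rigid(rng)
            chain = chains[c]
            new_residues = list(chain.residues)
            for seg, (a, b) in zip(tmpl.segments, windows):
                coords = seg.reshape(-1, 3) @ rot.T + trans
                coords = coords + rng.normal(0.0, planted.jitter, coords.shape)
                coords = coords.reshape(-1, 4, 3)
                for k, p in enumerate(range(a, b + 1)):
                    old = new_residues[p]
                    new_residues[p] = Residue(old.aa, coords[k], old.author_number)
            seed_pos = windows[tmpl.seed_segment][0] + tmpl.seed_offset
            if planted.sequence_model != "background":
                _, truth, p0 = planted.sequence_model
                aa = _sample_seed_aa(truth, p0, rng)
                old = new_residues[seed_pos]
                new_residues[seed_pos] = Residue(aa, old.coords, old.author_number)
            chains[c] = BackboneStructure(chain.chain_id, new_residues, chain.source_id)
            log.append(
                Placement(chains[c].source_id, tuple(windows), seed_pos,
                          chains[c].residues[seed_pos].aa)
            )
    db = database_from_structures(chains)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for s in db.entries:
            fname = f"{s.source_id}.pdb"
            write_pdb_backbone(s, out_dir / fname)
            manifest.append(f"{s.source_id}\t{fname}\t{s.chain_id}")
        (out_dir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    return db, log


def sample_ensemble(
    truth: EPSet,
    term: Term,
    n: int,
    P0: AminoAcidDistribution,
    seed: int = 0,
    nominal_cutoff: float = 0.5,
    context_probs: np.ndarray | None = None,
) -> MatchEnsemble:
    """Boltzmann-sample a pseudo-match ensemble from known energy parameters.

    Contact contexts are drawn i.i.d. from P0 (or ``context_probs``), the
    seed amino acid from the model's softmax given that context, all other
    positions from P0; RMSD values are uniform below the nominal cutoff.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cprobs = context_probs if context_probs is not None else P0.freq
    positions = term.positions
    cidx = term.contact_indices()
    seed_idx = term.seed_index
    matches = []
    rmsds = np.sort(rng.uniform(0.0, nominal_cutoff, size=n))
    for k in range(n):
        seq = list(random_sequence(len(positions), rng, P0))
        ctx = {}
        for j in term.contacts:
            yi = int(rng.choice(20, p=cprobs))
            seq[cidx[j]] = AMINO_ACIDS[yi]
            ctx[j] = yi
        seq[seed_idx] = _sample_seed_aa(truth, P0, rng, ctx)
        seq = "".join(seq)
        matches.append(
            Match(
                source_id=f"sample{k:06d}",
                aligned_positions=tuple(positions),
                rmsd=float(rmsds[k]),
                sequence=seq,
                seed_aa=seq[seed_idx],
            )
        )
    return MatchEnsemble(term, matches, nominal_cutoff)


def make_fitness_table(
    true_ddg: dict[str, float],
    refs: list[str],
    depth: int = 100_000,
    seed: int = 0,
    w_b: float = 0.8,
    w_ref: float = 0.5,
    noiseless: bool = False,
    violations: dict[str, str] | None = None,
) -> "CountTable":
    """Invert the fitness-to-ddG transformation into a synthetic count table.

    Every single mutation gets fitness ``w_b``; each reference gets
    ``w_ref``; the double-mutant fitness W_AB is solved from the target
    ddG so the estimator recovers it exactly in the noiseless limit.
    Counts are Poisson at the given sequencing depth unless ``noiseless``.
    ``violations`` maps a variant to one of the three filter names to
    plant a row each quality filter must reject.
    """
    from termddg.fitness_ddg import (
        FILTER_FITNESS_ORDER,
        FILTER_LOW_COUNT,
        FILTER_LOW_WB,
        CountTable,
    )

    if depth < 1000:
        raise ValueError("depth must be >= 1000")
    violations = violations or {}
    rng = np.random.default_rng(seed)
    expected: dict[str, tuple[float, float]] = {}

    def set_variant(label: str, W: float, n_input: float | None = None) -> None:
        n_in = float(depth if n_input is None else n_input)
        # as-printed orientation: W = (N_in / N_sel) * (wt_sel / wt_in); equal
        # wt counts make W = N_in / N_sel.
        expected[label] = (n_in, n_in / W)

    for a in refs:
        set_variant(a, w_ref)
    for b, ddg in true_ddg.items():
        wb = w_b
        if violations.get(b) == FILTER_LOW_WB:
            wb = 0.15
        set_variant(b, wb)
        for a in refs:
            q = ddg - math.log((1.0 - w_ref) / w_ref)
            w_ab = wb / (1.0 + math.exp(-q))
            label = "/".join(sorted([a, b]))
            if violations.get(b) == FILTER_FITNESS_ORDER:
                set_variant(label, wb * 1.2)
            elif violations.get(b) == FILTER_LOW_COUNT:
                set_variant(label, w_ab, n_input=50)
            else:
                set_variant(label, w_ab)

    rows = {}
    for label, (n_in, n_sel) in expected.items():
        if noiseless:
            # the noiseless limit works with expected (real-valued) counts
            rows[label] = (n_in, n_sel)
        else:
            rows[label] = (int(rng.poisson(n_in)), int(rng.poisson(n_sel)))
    return CountTable(rows, (depth, depth))
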