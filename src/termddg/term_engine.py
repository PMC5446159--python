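"""TERM definition, sub-TERM enumeration, structure-database motif search,
and match-ensemble filtering.

A TERM is the local backbone segment around a seed residue together with
the segments around every position poised to contact it. Sub-TERMs are
induced by contact subsets; an order-k sub-TERM (k >= 2) is only searched
once all of its order-(k-1) constituents have accumulated more than a
gate count of matches, since complex motifs without well-populated parts
cannot be well represented either.

The search maps each motif segment onto contiguous backbone windows of a
database chain (non-overlapping, order-free across the chain) and keeps
placements whose full-backbone optimal-superposition RMSD is within the
cutoff. A per-segment RMSD lower bound prunes candidate windows without
ever discarding a true match: the full-motif squared deviation restricted
to one segment can never be below that segment's own optimal fit, so
sqrt(sum_k N_k r_k^2 / N) <= cutoff is necessary for any placement.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from termddg.structure_io import (
    BackboneStructure,
    StructureDatabase,
    superpose_rmsd,
)

GATE_COUNT = 100
DEFAULT_FLANK = 2
MAX_MATCHES = 20000


@dataclass(frozen=True)
class Term:
    """A (sub-)TERM: seed position, contact subset, induced backbone segments."""

    seed: int
    contacts: tuple[int, ...]
    segments: tuple[tuple[int, int], ...]  # inclusive [start, end] intervals
    native_sequence: str

    @property
    def order(self) -> int:
        return len(self.contacts)

    @property
    def positions(self) -> list[int]:
        return [p for a, b in self.segments for p in range(a, b + 1)]

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    @property
    def seed_index(self) -> int:
        """Index of the seed within the flattened TERM positions."""
        return self.positions.index(self.seed)

    def contact_indices(self) -> dict[int, int]:
        """Structure position of each contact -> its index in TERM positions."""
        pos = self.positions
        return {j: pos.index(j) for j in self.contacts}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "contacts": list(self.contacts),
                "segments": [list(s) for s in self.segments],
                "native_sequence": self.native_sequence,
            }
        )


@dataclass(frozen=True)
class Match:
    """One structural match: source chain, per-TERM-residue alignment, RMSD."""

    source_id: str
    aligned_positions: tuple[int, ...]
    rmsd: float
    sequence: str
    seed_aa: str


@dataclass
class MatchEnsemble:
    term: Term
    matches: list[Match]
    cutoff_used: float

    def __len__(self) -> int:
        return len(self.matches)

    def sorted(self) -> "MatchEnsemble":
        ms = sorted(self.matches, key=lambda m: (m.rmsd, m.source_id, m.aligned_positions))
        return MatchEnsemble(self.term, ms, self.cutoff_used)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["source_id\trmsd\taligned_positions\tsequence"]
        for m in self.matches:
            lines.append(
                f"{m.source_id}\t{m.rmsd:.6f}\t{','.join(map(str, m.aligned_positions))}\t{m.sequence}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of inclusive intervals; overlapping or adjacent intervals merge."""
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return tuple((a, b) for a, b in out)


def define_term(
    structure: BackboneStructure,
    i: int,
    contacts: list[int] | tuple[int, ...],
    flank: int = DEFAULT_FLANK,
) -> Term:
    """Build the (sub-)TERM around seed i from a set of contacting positions.

    Each covered position contributes the interval [p - flank, p + flank]
    clipped to the chain; overlapping or adjacent intervals merge into one
    backbone segment.
    """
    L = len(structure)
    if not 0 <= i < L:
        raise IndexError(f"seed {i} out of range")
    for c in contacts:
        if not 0 <= c < L:
            raise IndexError(f"contact {c} out of range")
    covered = [i] + sorted(contacts)
    intervals = [(max(0, p - flank), min(L - 1, p + flank)) for p in covered]
    segments = merge_intervals(intervals)
    seq = "".join(structure.residues[p].aa for a, b in segments for p in range(a, b + 1))
    return Term(seed=i, contacts=tuple(sorted(contacts)), segments=segments, native_sequence=seq)


def enumerate_subterms(
    structure: BackboneStructure,
    i: int,
    C: list[int] | tuple[int, ...],
    flank: int = DEFAULT_FLANK,
    match_counts: dict[tuple[int, ...], int] | None = None,
    gate_count: int = GATE_COUNT,
    max_order: int | None = None,
) -> list[Term]:
    """Emit the searchable sub-TERMs around seed i, in deterministic order.

    Order-0 and all order-1 sub-TERMs are emitted unconditionally. An
    order-k sub-TERM (k >= 2) is emitted only when every one of its
    order-(k-1) contact subsets has a recorded match count exceeding
    ``gate_count`` in ``match_counts`` (populated lazily by the caller as
    searches complete). Ordering: by order, then lexicographic subset.
    """
    match_counts = match_counts or {}
    C = tuple(sorted(C))
    top = len(C) if max_order is None else min(max_order, len(C))
    out: list[Term] = []
    for k in range(top + 1):
        for subset in itertools.combinations(C, k):
            if k >= 2:
                parents_ok = all(
                    match_counts.get(parent, 0) > gate_count
                    for parent in itertools.combinations(subset, k - 1)
                )
                if not parents_ok:
                    continue
            out.append(define_term(structure, i, list(subset), flank))
    return out


@dataclass(frozen=True)
class CutoffParams:
    base: float = 0.5
    per_segment: float = 0.3
    per_residue: float = 0.1


def rmsd_cutoff(term: Term, params: CutoffParams = CutoffParams()) -> float:
    """Search RMSD cutoff growing with motif size and segment complexity."""
    n_seg = len(term.segments)
    n_res = term.n_residues
    return params.base + params.per_segment * (n_seg - 1) + params.per_residue * math.log(n_res)


def _segment_window_rmsds(seg_coords: np.ndarray, chain_coords: np.ndarray, n_res: int) -> np.ndarray:
    """Optimal-superposition RMSD of one segment against every window of a chain."""
    L = chain_coords.shape[0] // 4
    n_windows = L - n_res + 1
    out = np.full(max(n_windows, 0), np.inf)
    for w in range(n_windows):
        win = chain_coords[4 * w : 4 * (w + n_res)]
        out[w] = superpose_rmsd(seg_coords, win)
    return out


def search_matches(
    term: Term,
    structure: BackboneStructure,
    db: StructureDatabase,
    cutoff: float,
    max_matches: int = MAX_MATCHES,
) -> MatchEnsemble:
    """All database placements of the term within the RMSD cutoff.

    Segments map to contiguous non-overlapping windows of a single chain;
    their order along the target chain is unconstrained. Candidate windows
    are pruned with the lossless per-segment lower bound before the full
    superposition is evaluated. The result is sorted by ascending RMSD
    (ties: source_id, aligned positions) and truncated to ``max_matches``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    seg_lengths = [b - a + 1 for a, b in term.segments]
    n_total = sum(seg_lengths)
    seg_coords = [
        structure.coords(range(a, b + 1)) for a, b in term.segments
    ]
    query = np.concatenate(seg_coords, axis=0)
    budget = n_total * cutoff * cutoff  # total allowed SSD per residue-count

    matches: list[Match] = []
    for entry in db.entries:
        L = len(entry)
        chain_coords = entry.coords()
        # per-segment candidate windows under the lossless bound
        cand: list[list[tuple[int, float]]] = []
        feasible = True
        for sc, n_res in zip(seg_coords, seg_lengths):
            if L < n_res:
                feasible = False
                break
            r = _segment_window_rmsds(sc, chain_coords, n_res)
            keep = [(w, n_res * r[w] ** 2) for w in range(len(r)) if n_res * r[w] ** 2 <= budget]
            if not keep:
                feasible = False
                break
            cand.append(keep)
        if not feasible:
            continue
        for combo in itertools.product(*cand):
            # non-overlapping windows
            spans = [(w, w + n - 1) for (w, _), n in zip(combo, seg_lengths)]
            spans_sorted = sorted(spans)
            if any(spans_sorted[k][1] >= spans_sorted[k + 1][0] for k in range(len(spans) - 1)):
                continue
            if sum(ssd for _, ssd in combo) > budget:
                continue
            target = np.concatenate(
                [chain_coords[4 * w : 4 * (w + n)] for (w, _), n in zip(combo, seg_lengths)],
                axis=0,
            )
            r = superpose_rmsd(query, target)
            if r <= cutoff:
                aligned = tuple(
                    w + k for (w, _), n in zip(combo, seg_lengths) for k in range(n)
                )
                seq = "".join(entry.residues[p].aa for p in aligned)
                seed_aa = seq[term.seed_index]
                matches.append(Match(entry.source_id, aligned, r, seq, seed_aa))
    matches.sort(key=lambda m: (m.rmsd, m.source_id, m.aligned_positions))
    return MatchEnsemble(term, matches[:max_matches], cutoff)


def _local_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Best local-alignment identity and aligned length between two sequences."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5
    if not seq_a or not seq_b:
        return 0.0, 0
    aln = aligner.align(seq_a, seq_b)
    if len(aln) == 0:
        return 0.0, 0
    best = aln[0]
    n_aligned = 0
    n_ident = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        n_aligned += a1 - a0
        n_ident += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y)
    ident = n_ident / n_aligned if n_aligned else 0.0
    return ident, n_aligned


def filter_homologs(
    ensemble: MatchEnsemble,
    query_sequence: str,
    db: StructureDatabase,
    id_threshold: float = 0.30,
    min_overlap: int = 30,
    query_source_id: str | None = None,
    exclude: set[str] | None = None,
) -> MatchEnsemble:
    """Drop matches from chains homologous to the query protein.

    A source chain is homologous if its best local alignment to the query
    reaches ``id_threshold`` identity over at least ``min_overlap`` aligned
    residues. The query's own chain (by source id or exact sequence) and
    any chain in ``exclude`` are always removed.
    """
    exclude = exclude or set()
    verdict: dict[str, bool] = {}
    kept = []
    for m in ensemble.matches:
        sid = m.source_id
        if sid not in verdict:
            if sid in exclude or sid == query_source_id:
                verdict[sid] = True
            else:
                seq = db.sequences.get(sid, "")
                if seq == query_sequence:
                    verdict[sid] = True
                else:
                    ident, n = _local_identity(seq, query_sequence)
                    verdict[sid] = n >= min_overlap and ident >= id_threshold
        if not verdict[sid]:
            kept.append(m)
    return MatchEnsemble(ensemble.term, kept, ensemble.cutoff_used)


def _seed_window(match: Match, term: Term, db: StructureDatabase, half: int) -> tuple[int, str]:
    """Window-length sequence centered on the match's seed in its source chain.

    Returns (offset of window start relative to seed, sequence), clipped at
    the chain ends.
    """
    seq = db.sequences[match.source_id]
    s = match.aligned_positions[term.seed_index]
    lo = max(0, s - half)
    hi = min(len(seq) - 1, s + half)
    return lo - s, seq[lo : hi + 1]


def _window_identity(off_a: int, win_a: str, off_b: int, win_b: str) -> float:
    """Ungapped identity over seed-relative offsets both windows possess."""
    n_common = 0
    n_match = 0
    for d in range(max(off_a, off_b), min(off_a + len(win_a), off_b + len(win_b))):
        n_common += 1
        if win_a[d - off_a] == win_b[d - off_b]:
            n_match += 1
    return n_match / n_common if n_common else 0.0


def cluster_redundancy(
    ensemble: MatchEnsemble,
    db: StructureDatabase,
    window: int = 31,
    id_threshold: float = 0.40,
) -> MatchEnsemble:
    """Greedy centroid clustering of seed-centered sequence windows.

    Matches are scanned in ascending-RMSD order (ties by source id); each
    joins the first existing cluster whose centroid window shares at least
    ``id_threshold`` ungapped identity, else founds a new cluster. Only the
    centroid (lowest-RMSD member) of each cluster survives.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    ordered = sorted(ensemble.matches, key=lambda m: (m.rmsd, m.source_id, m.aligned_positions))
    centroids: list[tuple[int, str, Match]] = []
    for m in ordered:
        off, win = _seed_window(m, ensemble.term, db, half)
        joined = False
        for c_off, c_win, _ in centroids:
            if _window_identity(off, win, c_off, c_win) >= id_threshold:
                joined = True
                break
        if not joined:
            centroids.append((off, win, m))
    survivors = sorted(
        (c[2] for c in centroids), key=lambda m: (m.rmsd, m.source_id, m.aligned_positions)
    )
    return MatchEnsemble(ensemble.term, survivors, ensemble.cutoff_used)
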