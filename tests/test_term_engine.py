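import itertools

import numpy as np
import pytest

from termddg.structure_io import database_from_structures, superpose_rmsd
from termddg.synthetic import (
    FixtureSpec,
    Planted,
    build_backbone_chain,
    make_backbone_db,
    make_motif_template,
    random_sequence,
    PHI_PSI,
)
from termddg.term_engine import (
    CutoffParams,
    Match,
    MatchEnsemble,
    cluster_redundancy,
    define_term,
    enumerate_subterms,
    filter_homologs,
    merge_intervals,
    rmsd_cutoff,
    search_matches,
)


@pytest.fixture
def chain40(rng):
    pp = np.tile(PHI_PSI["helix"], (40, 1))
    return build_backbone_chain(pp, random_sequence(40, rng), source_id="q_A")


class TestDefineTerm:
    def test_no_contacts_single_segment(self, chain40):
        t = define_term(chain40, 20, [], flank=2)
        assert t.segments == ((18, 22),)
        assert t.order == 0
        assert t.n_residues == 5
        assert t.native_sequence == chain40.sequence[18:23]

    def test_overlapping_intervals_merge(self, chain40):
        t = define_term(chain40, 10, [12], flank=2)
        assert t.segments == ((8, 14),)

    def test_adjacent_intervals_merge(self, chain40):
        t = define_term(chain40, 10, [15], flank=2)
        # [8,12] and [13,17] are contiguous -> one segment
        assert t.segments == ((8, 17),)

    def test_clipping_at_chain_start(self, chain40):
        t = define_term(chain40, 1, [], flank=2)
        assert t.segments == ((0, 3),)

    def test_disjoint_contacts_two_segments(self, chain40):
        t = define_term(chain40, 10, [25], flank=2)
        assert t.segments == ((8, 12), (23, 27))
        assert t.seed_index == 2
        assert t.contact_indices()[25] == 7

    def test_out_of_range_raises(self, chain40):
        with pytest.raises(IndexError):
            define_term(chain40, 99, [])

    def test_interval_union_oracle(self, rng):
        for _ in range(50):
            points = sorted(rng.integers(0, 40, size=rng.integers(1, 6)))
            intervals = [(max(0, p - 2), min(39, p + 2)) for p in points]
            merged = merge_intervals(intervals)
            covered = sorted({x for a, b in intervals for x in range(a, b + 1)})
            flat = [x for a, b in merged for x in range(a, b + 1)]
            assert flat == covered
            # pairwise disjoint, sorted, non-adjacent
            for (a1, b1), (a2, b2) in zip(merged, merged[1:]):
                assert b1 + 1 < a2


class TestEnumerateSubterms:
    def test_all_emitted_when_counts_high(self, chain40):
        counts = {(5,): 200, (25,): 200}
        terms = enumerate_subterms(chain40, 10, [5, 25], match_counts=counts)
        assert [t.contacts for t in terms] == [(), (5,), (25,), (5, 25)]

    def test_gate_suppresses_order2(self, chain40):
        counts = {(5,): 50, (25,): 200}
        terms = enumerate_subterms(chain40, 10, [5, 25], match_counts=counts)
        assert [t.contacts for t in terms] == [(), (5,), (25,)]

    def test_gate_at_exactly_100_suppresses(self, chain40):
        counts = {(5,): 100, (25,): 200}
        terms = enumerate_subterms(chain40, 10, [5, 25], match_counts=counts)
        assert (5, 25) not in [t.contacts for t in terms]

    def test_empty_contacts_only_order0(self, chain40):
        terms = enumerate_subterms(chain40, 10, [])
        assert len(terms) == 1 and terms[0].order == 0

    def test_order3_needs_all_parents(self, chain40):
        C = [5, 20, 30]
        counts = {c: 200 for c in [(5,), (20,), (30,), (5, 20), (5, 30)]}
        counts[(20, 30)] = 80  # one order-2 parent below the gate
        terms = enumerate_subterms(chain40, 10, C, match_counts=counts)
        assert (5, 20, 30) not in [t.contacts for t in terms]
        counts[(20, 30)] = 150
        terms = enumerate_subterms(chain40, 10, C, match_counts=counts)
        assert [t.contacts for t in terms][-1] == (5, 20, 30)
        assert len(terms) == 2 ** 3


class TestRmsdCutoff:
    def test_default_formula(self, chain40):
        t = define_term(chain40, 20, [], flank=2)  # one 5-residue segment
        assert rmsd_cutoff(t) == pytest.approx(0.5 + 0.1 * np.log(5))

    def test_more_segments_larger_cutoff(self, chain40):
        t1 = define_term(chain40, 10, [25], flank=2)
        # same residue count in one segment: 10 residues contiguous
        t2 = define_term(chain40, 10, [15], flank=2)
        assert t1.n_residues == t2.n_residues == 10
        assert rmsd_cutoff(t1) > rmsd_cutoff(t2)

    def test_zero_increments_give_base(self, chain40):
        params = CutoffParams(base=0.7, per_segment=0.0, per_residue=0.0)
        for contacts in ([], [25], [25, 33]):
            t = define_term(chain40, 10, contacts)
            assert rmsd_cutoff(t, params) == pytest.approx(0.7)


def brute_force_search(term, structure, db, cutoff):
    """Exhaustive all-placement oracle."""
    seg_len = [b - a + 1 for a, b in term.segments]
    q = np.concatenate([structure.coords(range(a, b + 1)) for a, b in term.segments])
    out = []
    for e in db.entries:
        L = len(e)
        cc = e.coords()
        for combo in itertools.product(*[range(L - n + 1) for n in seg_len]):
            spans = sorted((w, w + n - 1) for w, n in zip(combo, seg_len))
            if any(spans[k][1] >= spans[k + 1][0] for k in range(len(spans) - 1)):
                continue
            tgt = np.concatenate([cc[4 * w: 4 * (w + n)] for w, n in zip(combo, seg_len)])
            r = superpose_rmsd(q, tgt)
            if r <= cutoff:
                out.append((e.source_id, combo, r))
    return out


class TestSearchMatches:
    def test_exact_copy_found_at_zero(self, rng):
        tmpl = make_motif_template(n_res=5, n_segments=1, rng=rng)
        spec = FixtureSpec(seed=5, n_chains=8, chain_length=50,
                           planted=[Planted(tmpl, copies=1, jitter=0.0)])
        db, log = make_backbone_db(spec)
        src = db[log[0].source_id]
        a, b = log[0].windows[0]
        term = define_term(src, log[0].seed_position, [], flank=2)
        ens = search_matches(term, src, db, cutoff=0.3)
        self_hits = [m for m in ens.matches if m.source_id == log[0].source_id
                     and m.aligned_positions[0] == term.segments[0][0]]
        assert self_hits and self_hits[0].rmsd == pytest.approx(0.0, abs=1e-9)

    def test_unrelated_db_tight_cutoff_empty(self, rng, chain40):
        # motif is irregular; pure-helix database has no matches at 0.3 A
        tmpl = make_motif_template(n_res=5, n_segments=1, rng=rng)
        qspec = FixtureSpec(seed=77, n_chains=1, chain_length=40,
                            planted=[Planted(tmpl, copies=1, jitter=0.0)])
        qdb, qlog = make_backbone_db(qspec)
        query = qdb.entries[0]
        pp = np.tile(PHI_PSI["helix"], (40, 1))
        helices = [build_backbone_chain(pp, random_sequence(40, rng), source_id=f"h{i}")
                   for i in range(5)]
        db = database_from_structures(helices)
        term = define_term(query, qlog[0].seed_position, [], flank=2)
        assert len(search_matches(term, query, db, cutoff=0.3)) == 0

    def test_matches_oracle_with_planted_noise(self, rng):
        tmpl = make_motif_template(n_res=5, n_segments=2, rng=rng)
        spec = FixtureSpec(seed=21, n_chains=12, chain_length=50,
                           planted=[Planted(tmpl, copies=7, jitter=0.2)])
        db, log = make_backbone_db(spec)
        qspec = FixtureSpec(seed=500, n_chains=1, chain_length=50,
                            planted=[Planted(tmpl, copies=1, jitter=0.0)])
        qdb, qlog = make_backbone_db(qspec)
        query = qdb.entries[0]
        w = sorted(qlog[0].windows)
        term = define_term(query, qlog[0].seed_position,
                           [w[-1][0] + 2] if w[-1][0] + 2 != qlog[0].seed_position else [w[0][0] + 2],
                           flank=2)
        cutoff = 0.8
        ens = search_matches(term, query, db, cutoff)
        oracle = brute_force_search(term, query, db, cutoff)
        got = sorted((m.source_id, m.aligned_positions, round(m.rmsd, 6)) for m in ens.matches)
        seg_len = [b - a + 1 for a, b in term.segments]
        exp = sorted(
            (sid, tuple(w0 + k for w0, n in zip(combo, seg_len) for k in range(n)), round(r, 6))
            for sid, combo, r in oracle
        )
        assert got == exp

    def test_sorted_and_capped(self, rng):
        tmpl = make_motif_template(n_res=5, n_segments=1, rng=rng)
        spec = FixtureSpec(seed=9, n_chains=10, chain_length=50,
                           planted=[Planted(tmpl, copies=6, jitter=0.3)])
        db, log = make_backbone_db(spec)
        src = db[log[0].source_id]
        term = define_term(src, log[0].seed_position, [], flank=2)
        ens = search_matches(term, src, db, cutoff=1.5, max_matches=3)
        assert len(ens) == 3
        rmsds = [m.rmsd for m in ens.matches]
        assert rmsds == sorted(rmsds)


def _mk_match(sid, positions, rmsd, seq, seed_idx):
    return Match(sid, tuple(positions), rmsd, seq, seq[seed_idx])


class TestFilterHomologs:
    def _setup(self, rng):
        pp = np.tile(PHI_PSI["helix"], (40, 1))
        chains = [build_backbone_chain(pp, random_sequence(40, rng), source_id=f"c{i}")
                  for i in range(3)]
        return chains

    def test_query_chain_removed(self, rng, chain40):
        db = database_from_structures(self._setup(rng) + [chain40])
        term = define_term(chain40, 20, [])
        m = _mk_match(chain40.source_id, range(18, 23), 0.0, chain40.sequence[18:23], 2)
        ens = MatchEnsemble(term, [m], 1.0)
        out = filter_homologs(ens, chain40.sequence, db, query_source_id=chain40.source_id)
        assert len(out) == 0

    def test_identical_subsequence_removed(self, rng, chain40):
        # a source sharing a 40-residue identical stretch with the query
        pp = np.tile(PHI_PSI["helix"], (40, 1))
        twin = build_backbone_chain(pp, chain40.sequence, source_id="twin")
        db = database_from_structures(self._setup(rng) + [twin])
        term = define_term(chain40, 20, [])
        m = _mk_match("twin", range(18, 23), 0.1, chain40.sequence[18:23], 2)
        out = filter_homologs(MatchEnsemble(term, [m], 1.0), chain40.sequence, db)
        assert len(out) == 0

    def test_unrelated_source_retained(self, rng, chain40):
        chains = self._setup(rng)
        db = database_from_structures(chains)
        term = define_term(chain40, 20, [])
        m = _mk_match("c0", range(5, 10), 0.1, chains[0].sequence[5:10], 2)
        out = filter_homologs(MatchEnsemble(term, [m], 1.0), chain40.sequence, db)
        assert len(out) == 1


class TestClusterRedundancy:
    def _db_with_sequences(self, seqs, rng):
        pp_fn = lambda L: np.tile(PHI_PSI["helix"], (L, 1))
        chains = [build_backbone_chain(pp_fn(len(s)), s, source_id=f"s{i}")
                  for i, s in enumerate(seqs)]
        return database_from_structures(chains), chains

    def test_identical_windows_keep_lowest_rmsd(self, rng, chain40):
        seq = random_sequence(40, rng)
        db, chains = self._db_with_sequences([seq, seq], rng)
        term = define_term(chain40, 20, [])
        m1 = _mk_match("s0", range(18, 23), 0.30, seq[18:23], 2)
        m2 = _mk_match("s1", range(18, 23), 0.10, seq[18:23], 2)
        out = cluster_redundancy(MatchEnsemble(term, [m1, m2], 1.0), db)
        assert len(out) == 1
        assert out.matches[0].rmsd == pytest.approx(0.10)

    def test_dissimilar_all_retained(self, rng, chain40):
        seqs = [random_sequence(40, np.random.default_rng(k)) for k in range(4)]
        db, _ = self._db_with_sequences(seqs, rng)
        term = define_term(chain40, 20, [])
        ms = [_mk_match(f"s{i}", range(18, 23), 0.1 * i, seqs[i][18:23], 2) for i in range(4)]
        out = cluster_redundancy(MatchEnsemble(term, ms, 1.0), db)
        assert len(out) == 4

    def test_two_planted_groups_match_allpairs_oracle(self, rng, chain40):
        base1 = random_sequence(40, np.random.default_rng(1))
        base2 = random_sequence(40, np.random.default_rng(2))
        seqs = [base1, base1, base1, base2, base2, base2]
        db, _ = self._db_with_sequences(seqs, rng)
        term = define_term(chain40, 20, [])
        ms = [_mk_match(f"s{i}", range(18, 23), 0.05 * (i + 1), seqs[i][18:23], 2)
              for i in range(6)]
        out = cluster_redundancy(MatchEnsemble(term, ms, 1.0), db)
        assert len(out) == 2
        assert {m.source_id for m in out.matches} == {"s0", "s3"}

    def test_pipeline_monotonicity(self, rng):
        tmpl = make_motif_template(n_res=5, n_segments=1, rng=rng)
        spec = FixtureSpec(seed=31, n_chains=10, chain_length=50,
                           planted=[Planted(tmpl, copies=5, jitter=0.25)])
        db, log = make_backbone_db(spec)
        src = db[log[0].source_id]
        term = define_term(src, log[0].seed_position, [])
        raw = search_matches(term, src, db, cutoff=1.0, max_matches=100)
        hom = filter_homologs(raw, src.sequence, db, query_source_id=src.source_id)
        clu = cluster_redundancy(hom, db)
        assert len(clu) <= len(hom) <= len(raw) <= 100

    def test_determinism(self, rng):
        tmpl = make_motif_template(n_res=5, n_segments=1, rng=rng)
        spec = FixtureSpec(seed=13, n_chains=10, chain_length=50,
                           planted=[Planted(tmpl, copies=4, jitter=0.2)])
        db, log = make_backbone_db(spec)
        src = db[log[0].source_id]
        term = define_term(src, log[0].seed_position, [])
        e1 = search_matches(term, src, db, cutoff=1.0)
        e2 = search_matches(term, src, db, cutoff=1.0)
        assert [(m.source_id, m.aligned_positions, m.rmsd) for m in e1.matches] == [
            (m.source_id, m.aligned_positions, m.rmsd) for m in e2.matches
        ]
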