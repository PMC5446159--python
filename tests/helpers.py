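"""Shared fixture builders used by several test modules."""

import numpy as np

from termddg.ep_model import EPSet
from termddg.structure_io import (
    AA_INDEX,
    AminoAcidDistribution,
    BackboneStructure,
    Residue,
)
from termddg.synthetic import (
    FixtureSpec,
    Planted,
    make_backbone_db,
    make_motif_template,
)


def sign_fixture(seed, favored="I", copies=40, n_chains=12):
    """Database with planted motif copies whose seed strongly prefers one
    amino acid, plus a query chain carrying the motif natively (seed
    mutated to the favored amino acid)."""
    p0 = AminoAcidDistribution.uniform()
    rng = np.random.default_rng(seed)
    tmpl = make_motif_template(n_res=5, n_segments=1, rng=rng)
    truth = EPSet.from_priors(())
    truth.sEP = np.zeros(20)
    truth.sEP[AA_INDEX[favored]] = -3.0
    planted = Planted(tmpl, copies=copies, jitter=0.15,
                      sequence_model=("boltzmann", truth, p0))
    spec = FixtureSpec(seed=seed, n_chains=n_chains, chain_length=50, planted=[planted])
    db, log = make_backbone_db(spec)
    qspec = FixtureSpec(seed=seed + 50_000, n_chains=1, chain_length=40,
                        planted=[Planted(tmpl, copies=1, jitter=0.0)])
    qdb, qlog = make_backbone_db(qspec)
    query = qdb.entries[0]
    sp = qlog[0].seed_position
    res = list(query.residues)
    res[sp] = Residue(favored, res[sp].coords, res[sp].author_number)
    query = BackboneStructure(query.chain_id, res, "query_A")
    return db, query, sp
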