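"""End-to-end orchestration: structure + mutation + database -> ddG report.

The flow per mutated position: compute the contact set by contact degree,
define the TERM and its sub-TERMs (order-gated), search the database for
backbone matches to each, prune homologs and local sequence redundancy,
fit the regularized energy parameters on the retained ensembles, and
report the predicted ddG with its ubiquity confidence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import termddg
from termddg.contacts import (
    CONTACT_THRESHOLD,
    ContactEngine,
    ContactPotential,
    FreedomTable,
    contact_potential,
    freedom_propensities,
)
from termddg.ep_model import (
    DEFAULT_LAMBDA,
    EnsembleCollection,
    EPSet,
    FitConfig,
    PredictionResult,
    W_CONST,
    count_occurrences,
    fit_eps,
    predict_ddg,
)
from termddg.rotamers import RotamerLibrary, default_library
from termddg.structure_io import (
    AMINO_ACIDS,
    BackboneStructure,
    StructureDatabase,
    read_pdb_backbone,
)
from termddg.term_engine import (
    CutoffParams,
    DEFAULT_FLANK,
    GATE_COUNT,
    MAX_MATCHES,
    MatchEnsemble,
    cluster_redundancy,
    define_term,
    enumerate_subterms,
    filter_homologs,
    rmsd_cutoff,
    search_matches,
)

logger = logging.getLogger(__name__)

MODEL_ORDER_CAPS = {"order0": 0, "order1": 1, "order2": 2, "standard": 2}


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the reference defaults."""

    lam: float = DEFAULT_LAMBDA
    model: str = "standard"  # standard/order2 | order1 | order0 | full | conpot | noprior
    flank: int = DEFAULT_FLANK
    contact_threshold: float = CONTACT_THRESHOLD
    match_cap: int = MAX_MATCHES
    gate_count: int = GATE_COUNT
    w_const: float = W_CONST
    cluster_window: int = 31
    cluster_id: float = 0.40
    homology_id: float = 0.30
    homology_overlap: int = 30
    cutoff_params: CutoffParams = field(default_factory=CutoffParams)
    clash_cutoff: float = 2.5
    seed: int = 0
    proceed_on_mismatch: bool = False

    def max_order(self) -> int | None:
        if self.model in MODEL_ORDER_CAPS:
            return MODEL_ORDER_CAPS[self.model]
        return None  # full, conpot, noprior: no cap

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cp = raw.pop("cutoff_params", None)
        cfg = cls(**raw)
        if cp:
            cfg.cutoff_params = CutoffParams(**cp)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class SubtermRow:
    order: int
    contacts: tuple[int, ...]
    n_raw: int
    n_post_homology: int
    n_post_cluster: int
    weight: float


@dataclass
class RunReport:
    mutation: str
    ddg: float
    ubiquity: float
    model_tag: str
    n_matches_total: int
    subterms: list[SubtermRow]
    config: dict
    version: str
    database_fingerprint: str
    conpot_fallback: bool = False
    wildtype_mismatch: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=1)

    def tsv_row(self) -> str:
        return (
            f"{self.mutation}\t{self.ddg:.4f}\t{self.ubiquity:.3f}\t"
            f"{len(self.subterms)}\t{self.n_matches_total}"
        )


def database_fingerprint(db: StructureDatabase) -> str:
    h = hashlib.sha256()
    for e in db.entries:
        h.update(f"{e.source_id}:{len(e)}:{e.sequence}".encode())
    return h.hexdigest()[:16]


MUTATION_RE = re.compile(r"^([A-Z])(\d+[A-Z]?)([A-Z])$")


def parse_mutation(spec: str) -> tuple[str, str, str]:
    m = MUTATION_RE.match(spec.strip())
    if not m:
        raise ValueError(f"cannot parse mutation {spec!r} (expected e.g. I8A)")
    return m.group(1), m.group(2), m.group(3)


class Predictor:
    """Holds the database-wide state (rotamer library, freedom propensities,
    contact potential) and an ensemble cache shared across predictions."""

    def __init__(
        self,
        db: StructureDatabase,
        config: RunConfig | None = None,
        lib: RotamerLibrary | None = None,
    ):
        self.db = db
        self.config = config or RunConfig()
        self.lib = lib or default_library()
        self.fingerprint = database_fingerprint(db)
        self._freedom_table: FreedomTable | None = None
        self._conpot: ContactPotential | None = None
        self._ensemble_cache: dict = {}

    @property
    def freedom_table(self) -> FreedomTable:
        if self._freedom_table is None:
            self._freedom_table = freedom_propensities(self.db, self.lib)
        return self._freedom_table

    @property
    def conpot(self) -> ContactPotential:
        if self._conpot is None:
            self._conpot = contact_potential(
                self.db, self.lib, self.freedom_table, self.config.contact_threshold
            )
        return self._conpot

    # -- ensemble gathering -------------------------------------------------

    def _search_cached(self, term, structure) -> MatchEnsemble:
        cutoff = rmsd_cutoff(term, self.config.cutoff_params)
        key = (self.fingerprint, term.segments, term.seed, round(cutoff, 9))
        if key not in self._ensemble_cache:
            self._ensemble_cache[key] = search_matches(
                term, structure, self.db, cutoff, self.config.match_cap
            )
        return self._ensemble_cache[key]

    def gather(
        self, structure: BackboneStructure, i: int, contacts: list[int]
    ) -> tuple[list, list[SubtermRow]]:
        """Search, filter and cluster ensembles for all gated sub-TERMs."""
        cfg = self.config
        match_counts: dict[tuple[int, ...], int] = {}
        gathered: list = []
        rows: list[SubtermRow] = []
        max_order = cfg.max_order()
        top = len(contacts) if max_order is None else min(max_order, len(contacts))
        searched: set[tuple[int, ...]] = set()
        for k in range(top + 1):
            terms = [
                t
                for t in enumerate_subterms(
                    structure, i, contacts, cfg.flank, match_counts, cfg.gate_count, top
                )
                if t.order == k and t.contacts not in searched
            ]
            for term in terms:
                searched.add(term.contacts)
                raw = self._search_cached(term, structure)
                match_counts[term.contacts] = len(raw)
                post_hom = filter_homologs(
                    raw,
                    structure.sequence,
                    self.db,
                    cfg.homology_id,
                    cfg.homology_overlap,
                    query_source_id=structure.source_id,
                )
                post_clu = cluster_redundancy(
                    post_hom, self.db, cfg.cluster_window, cfg.cluster_id
                )
                w = len(post_clu) / (len(post_clu) + cfg.w_const)
                gathered.append((term, post_clu))
                rows.append(
                    SubtermRow(term.order, term.contacts, len(raw), len(post_hom), len(post_clu), w)
                )
        return gathered, rows

    # -- prediction ---------------------------------------------------------

    def _priors(self, contacts: list[int], degrees: dict[int, float]) -> EPSet:
        if self.config.model == "noprior":
            return EPSet.from_priors(tuple(sorted(contacts)))
        pair = {j: self.conpot.matrix(degrees[j]) for j in contacts}
        return EPSet.from_priors(tuple(sorted(contacts)), pair)

    def fit_position(
        self, structure: BackboneStructure, i: int
    ) -> tuple[EPSet, dict[int, str], list[SubtermRow], bool]:
        """Fit energy parameters at one position; returns (eps, native
        context, per-sub-TERM table, conpot-fallback flag)."""
        cfg = self.config
        engine = ContactEngine(
            structure, self.lib, self.db.background, clash_cutoff=cfg.clash_cutoff
        )
        contacts = engine.contact_set(i, cfg.contact_threshold)
        degrees = {j: engine.contact_degree(i, j) for j in contacts}
        sigma0 = {j: structure.residues[j].aa for j in contacts}
        priors = self._priors(contacts, degrees)
        if cfg.model == "conpot":
            eps = priors.copy()
            eps.occ_sEP = np.zeros(20)
            eps.occ_pEP = {j: np.zeros((20, 20)) for j in eps.contacts}
            return eps, sigma0, [], False
        gathered, rows = self.gather(structure, i, contacts)
        collection = EnsembleCollection(gathered, sigma0, cfg.w_const)
        total = sum(len(e.matches) for _, e in gathered)
        if total == 0:
            logger.warning("no matches at any order for position %d; ConPot fallback", i)
            eps = priors.copy()
            count_occurrences(eps, collection)
            return eps, sigma0, rows, True
        fit_cfg = FitConfig(lam=cfg.lam)
        eps = fit_eps(collection, priors, cfg.lam, self.db.background, fit_cfg)
        return eps, sigma0, rows, False

    def predict(
        self, structure: BackboneStructure, i: int, u: str, v: str
    ) -> tuple[PredictionResult, list[SubtermRow], bool]:
        eps, sigma0, rows, fallback = self.fit_position(structure, i)
        result = predict_ddg(eps, sigma0, u, v, model_tag=self.config.model)
        return result, rows, fallback


def resolve_position(structure: BackboneStructure, author_number: str) -> int:
    for idx, r in enumerate(structure.residues):
        if r.author_number == author_number:
            return idx
    raise KeyError(f"residue {author_number} not resolved in structure")


def run_prediction(
    pdb: str | Path | BackboneStructure,
    chain: str,
    mutation: str,
    db: StructureDatabase,
    config: RunConfig | None = None,
    predictor: Predictor | None = None,
) -> RunReport:
    """The full pipeline for a single point mutation (e.g. ``I8A``)."""
    config = config or (predictor.config if predictor else RunConfig())
    structure = pdb if isinstance(pdb, BackboneStructure) else read_pdb_backbone(pdb, chain)
    wt, author_num, mut = parse_mutation(mutation)
    i = resolve_position(structure, author_num)
    mismatch = structure.residues[i].aa != wt
    if mismatch:
        msg = (
            f"structure has {structure.residues[i].aa} at {author_num}, "
            f"mutation says {wt}"
        )
        if not config.proceed_on_mismatch:
            raise ValueError(msg)
        warnings.warn(msg)
    predictor = predictor or Predictor(db, config)
    result, rows, fallback = predictor.predict(structure, i, wt, mut)
    return RunReport(
        mutation=mutation,
        ddg=result.ddg,
        ubiquity=result.ubiquity,
        model_tag=result.model_tag,
        n_matches_total=sum(r.n_post_cluster for r in rows),
        subterms=rows,
        config=config.echo(),
        version=termddg.__version__,
        database_fingerprint=predictor.fingerprint,
        conpot_fallback=fallback,
        wildtype_mismatch=mismatch,
    )


def run_scan(
    pdb: str | Path | BackboneStructure,
    chain: str,
    db: StructureDatabase,
    config: RunConfig | None = None,
) -> list[RunReport]:
    """All 19 substitutions at every position; per-position searches and
    fits are executed once and reused across the 19 rows."""
    config = config or RunConfig()
    structure = pdb if isinstance(pdb, BackboneStructure) else read_pdb_backbone(pdb, chain)
    predictor = Predictor(db, config)
    reports = []
    for i, res in enumerate(structure.residues):
        eps, sigma0, rows, fallback = predictor.fit_position(structure, i)
        for v in AMINO_ACIDS:
            if v == res.aa:
                continue
            result = predict_ddg(eps, sigma0, res.aa, v, model_tag=config.model)
            reports.append(
                RunReport(
                    mutation=f"{res.aa}{res.author_number or i + 1}{v}",
                    ddg=result.ddg,
                    ubiquity=result.ubiquity,
                    model_tag=result.model_tag,
                    n_matches_total=sum(r.n_post_cluster for r in rows),
                    subterms=rows,
                    config=config.echo(),
                    version=termddg.__version__,
                    database_fingerprint=predictor.fingerprint,
                    conpot_fallback=fallback,
                )
            )
    return reports
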