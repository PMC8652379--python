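"""Synthetic study generator with planted PK-cancer signal.

Emulates the five input tables the pipeline consumes — articles,
concept annotations, MeSH hierarchy, kinase-inhibitor activities and
clinical trials — at desk scale, with known ground truth:

* a set of "true" (PK, cancer) pairs; each receives signal documents in
  which the two concept mentions co-occur alongside a pair-specific cluster
  of context words (difference-vector classification needs relational
  structure, not mere proximity, so both knobs exist);
* background documents of random vocabulary, half of them carrying one
  random concept mention, so non-true concepts still clear the embedding
  frequency floor;
* one inhibitor per true pair with a sub-threshold (<0.03 uM) activity on
  the pair's kinase plus decoy supra-threshold activities; a few inhibitors
  exceed the per-inhibitor target cap to exercise the top-n filter;
* trials per true pair across phases, with the phase-IV start year drawn
  from the configured range (this year decides whether the pair lands in
  the historical training or test era); decoy trials for non-true pairs
  appear only in phases I-II.

Everything is reproducible from the config seed and writes the same plain
TSV/JSONL dialects the real readers parse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_corpus",
    "mesh_hierarchy_jsonl",
    "generate_catalog_tables",
    "end_to_end_fixture",
    "pk_token_map",
    "cancer_token_map",
]

SEARCH_ROOT_CANCER = "D009369"  # Neoplasms
SEARCH_ROOT_KINASE = "D011494"  # Protein Kinases
_KINASE_TAG = "D011495"  # generic protein-kinase subcategory used for tagging


@dataclass(frozen=True)
class SynthConfig:
    n_pk: int = 30
    n_cancer: int = 30
    n_true_pairs: int = 40
    docs_per_true_pair: int = 60
    background_docs: int = 3000
    vocab_size: int = 400
    context_words_per_pair: int = 6
    doc_length: int = 24
    pki_count: int = 50
    trials_per_true_pair: int = 3
    cap_exceeders: int = 2
    year_range: tuple[int, int] = (2000, 2020)
    #: fraction of kinases/cancers that are trial-active; true pairs are drawn
    #: from the active x active subgrid, mirroring the real literature where
    #: druggable kinases and trial-treated cancers are minorities
    active_fraction: float = 0.4
    #: size of each side-specific shared relation vocabulary (kinase-side and
    #: cancer-side words that appear only in signal documents)
    relation_words: int = 12
    seed: int = 7

    def __post_init__(self) -> None:
        for name in (
            "n_pk", "n_cancer", "n_true_pairs", "docs_per_true_pair",
            "background_docs", "vocab_size", "context_words_per_pair",
            "doc_length", "pki_count", "trials_per_true_pair", "cap_exceeders",
            "relation_words",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")
        if self.n_true_pairs > self.n_active_pk * self.n_active_cancer:
            raise ValueError("n_true_pairs exceeds the active PK x cancer subgrid")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("empty year_range")
        if self.pki_count < self.n_true_pairs + self.cap_exceeders:
            raise ValueError("pki_count must cover true pairs and cap exceeders")

    @property
    def n_active_pk(self) -> int:
        return max(1, int(round(self.active_fraction * self.n_pk)))

    @property
    def n_active_cancer(self) -> int:
        return max(1, int(round(self.active_fraction * self.n_cancer)))


@dataclass
class SynthTruth:
    """The planted ground truth: true pairs and their phase-IV years."""

    true_pairs: set[tuple[str, str]]
    pair_year: dict[tuple[str, str], int] = field(default_factory=dict)
    pair_pki: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_pairs": sorted(list(p) for p in self.true_pairs),
                "pair_year": {f"{pk}|{c}": y for (pk, c), y in sorted(self.pair_year.items())},
                "pair_pki": {f"{pk}|{c}": d for (pk, c), d in sorted(self.pair_pki.items())},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SynthTruth":
        data = json.loads(text)
        pairs = {tuple(p) for p in data["true_pairs"]}
        years = {tuple(k.split("|")): v for k, v in data["pair_year"].items()}
        pkis = {tuple(k.split("|")): v for k, v in data.get("pair_pki", {}).items()}
        return cls(true_pairs=pairs, pair_year=years, pair_pki=pkis)


# -- entity naming ----------------------------------------------------------

def _pk_symbols(config: SynthConfig) -> list[str]:
    return [f"PK{i:02d}" for i in range(1, config.n_pk + 1)]


def _cancer_ids(config: SynthConfig) -> list[str]:
    return [f"D5{i:05d}" for i in range(1, config.n_cancer + 1)]


def _gene_id(pk: str) -> str:
    return str(1000 + int(pk[2:]))


def pk_token_map(config: SynthConfig) -> dict[str, str]:
    """PK symbol -> corpus concept token (NCBI gene style)."""
    return {pk: f"ncbigene{_gene_id(pk)}" for pk in _pk_symbols(config)}


def cancer_token_map(config: SynthConfig) -> dict[str, str]:
    """Cancer MeSH id -> corpus concept token."""
    return {c: f"mesh{c.lower()}" for c in _cancer_ids(config)}


def _pk_surface(pk: str) -> str:
    return pk  # the symbol itself is the annotated mention


def _cancer_surface(cancer_id: str) -> str:
    return f"neoplasm{int(cancer_id[1:]) % 100000:02d}"


# -- corpus ----------------------------------------------------------------

def mesh_hierarchy_jsonl(config: SynthConfig) -> str:
    """JSON-lines hierarchy: two search roots plus one node per cancer."""
    lines = [
        {"id": SEARCH_ROOT_CANCER, "label": "Neoplasms", "synonyms": ["Tumors"], "parents": []},
        {"id": SEARCH_ROOT_KINASE, "label": "Protein Kinases", "synonyms": [], "parents": []},
        {
            "id": _KINASE_TAG,
            "label": "Synthetic Kinase Studies",
            "synonyms": [],
            "parents": [SEARCH_ROOT_KINASE],
        },
    ]
    for cid in _cancer_ids(config):
        lines.append(
            {
                "id": cid,
                "label": f"Neoplasm type {int(cid[1:]) % 100000}",
                "synonyms": [_cancer_surface(cid)],
                "parents": [SEARCH_ROOT_CANCER],
            }
        )
    return "\n".join(json.dumps(l) for l in lines) + "\n"


def _sample_true_pairs(config: SynthConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    # true pairs live on the active x active subgrid (druggable kinases,
    # trial-treated cancers); the first n_active of each side are active
    pks = _pk_symbols(config)[: config.n_active_pk]
    cancers = _cancer_ids(config)[: config.n_active_cancer]
    grid = [(pk, c) for pk in pks for c in cancers]
    idx = rng.choice(len(grid), size=config.n_true_pairs, replace=False)
    return [grid[i] for i in sorted(idx)]


def generate_corpus(config: SynthConfig = SynthConfig()) -> tuple[str, str, SynthTruth]:
    """Article and annotation tables (TSV text) plus the planted truth.

    Signal documents for each true pair contain the pair's two concept
    mentions plus its context-word cluster embedded in random filler;
    every document is MeSH-tagged so it passes relevance filtering.
    """
    rng = np.random.default_rng(config.seed)
    true_pairs = _sample_true_pairs(config, rng)
    years = rng.integers(config.year_range[0], config.year_range[1] + 1,
                         size=len(true_pairs))
    truth = SynthTruth(
        true_pairs=set(true_pairs),
        pair_year={p: int(y) for p, y in zip(true_pairs, years)},
        pair_pki={p: f"PKI{i:03d}" for i, p in enumerate(true_pairs, 1)},
    )

    vocab = [f"w{i:03d}" for i in range(config.vocab_size)]
    ctx_words = {
        pair: [f"ctx{i:03d}x{j}" for j in range(config.context_words_per_pair)]
        for i, pair in enumerate(true_pairs)
    }
    # side-specific shared relation vocabularies: kinase-side words appear
    # only adjacent to PK mentions, cancer-side words only adjacent to cancer
    # mentions, so the two concept classes acquire distinct context signatures
    kin_words = [f"kin{j:02d}" for j in range(config.relation_words)]
    dis_words = [f"dis{j:02d}" for j in range(config.relation_words)]
    title = "synthetic abstract"
    art_rows: list[str] = []
    ann_rows: list[str] = []
    pmid = 0

    def emit(abstract_words, mentions, mesh_tag, year):
        # mentions: list of (word_index_in_abstract, category, concept_id)
        nonlocal pmid
        pmid += 1
        pid = str(pmid)
        abstract = " ".join(abstract_words)
        art_rows.append(f"{pid}\t{year}\t{mesh_tag}\t\t{title}\t{abstract}")
        base = len(title) + 1  # offsets live in "title abstract" space
        pos = base
        starts = []
        for w in abstract_words:
            starts.append(pos)
            pos += len(w) + 1
        for widx, category, concept_id in mentions:
            s = starts[widx]
            ann_rows.append(
                f"{pid}\t{s}\t{s + len(abstract_words[widx])}\t{category}\t{concept_id}"
            )

    for pair in true_pairs:
        pk, cancer = pair
        half = config.context_words_per_pair // 2
        for _ in range(config.docs_per_true_pair):
            # two-sided layout: [kin words, PK, pair ctx] .. gap .. [dis
            # words, cancer, pair ctx].  The pair cluster spans both halves
            # (it cancels in the true pair's difference vector); the side
            # vocabularies stay adjacent to their own concept class.
            kin = [kin_words[i] for i in rng.choice(len(kin_words), 3, replace=False)]
            dis = [dis_words[i] for i in rng.choice(len(dis_words), 3, replace=False)]
            # the cluster split alternates randomly per document so that over
            # many documents each cluster word co-occurs equally with both
            # concepts and the pair component cancels in f(pk) - f(cancer)
            ctx = [ctx_words[pair][i] for i in rng.permutation(config.context_words_per_pair)]
            pk_half = kin + [(_pk_surface(pk), "gene", _gene_id(pk))] + ctx[:half]
            ca_half = dis + [(_cancer_surface(cancer), "disease", cancer)] + ctx[half:]
            n_core = len(pk_half) + len(ca_half)
            n_filler = max(config.doc_length - n_core, 6)
            filler = [vocab[i] for i in rng.integers(0, len(vocab), size=n_filler)]
            gap = 6  # keeps the two halves mostly outside each other's window
            words, mentions = [], []
            for item in pk_half:
                if isinstance(item, tuple):
                    mentions.append((len(words), item[1], item[2]))
                    words.append(item[0])
                else:
                    words.append(item)
            words.extend(filler[:gap])
            for item in ca_half:
                if isinstance(item, tuple):
                    mentions.append((len(words), item[1], item[2]))
                    words.append(item[0])
                else:
                    words.append(item)
            words.extend(filler[gap:])
            year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
            emit(words, mentions, cancer, year)

    pks, cancers = _pk_symbols(config), _cancer_ids(config)
    for _ in range(config.background_docs):
        words = [vocab[i] for i in rng.integers(0, len(vocab), size=config.doc_length)]
        mentions = []
        mesh_tag = _KINASE_TAG
        if rng.random() < 0.5:  # one random single concept mention
            widx = int(rng.integers(0, len(words)))
            if rng.random() < 0.5:
                pk = pks[int(rng.integers(0, len(pks)))]
                words[widx] = _pk_surface(pk)
                mentions.append((widx, "gene", _gene_id(pk)))
            else:
                cancer = cancers[int(rng.integers(0, len(cancers)))]
                words[widx] = _cancer_surface(cancer)
                mentions.append((widx, "disease", cancer))
                mesh_tag = cancer
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        emit(words, mentions, mesh_tag, year)

    articles_tsv = "\n".join(art_rows) + ("\n" if art_rows else "")
    annotations_tsv = "\n".join(ann_rows) + ("\n" if ann_rows else "")
    return articles_tsv, annotations_tsv, truth


# -- catalog tables ---------------------------------------------------------

def generate_catalog_tables(
    config: SynthConfig, truth: SynthTruth
) -> tuple[str, str]:
    """Activity and trial tables (TSV text) consistent with the truth.

    One inhibitor per true pair carries a sub-threshold activity for the
    pair's kinase (plus decoy supra-threshold activities); ``cap_exceeders``
    inhibitors get n_pk+2 sub-threshold targets to exercise the top-n cap;
    each true pair receives a phase-IV trial at its truth year plus
    earlier-phase trials; decoy trials for non-true pairs stay in phases
    I-II.
    """
    rng = np.random.default_rng(config.seed + 1)
    pks, cancers = _pk_symbols(config), _cancer_ids(config)
    act_rows = ["pki\tpk\taffinity_um\tpmid"]
    trial_rows = ["nct_id\tpki\tcancer_mesh\tphase\tstart_year\tcompletion_year"]
    nct = 0

    def trial(pki, cancer, phase, year):
        nonlocal nct
        nct += 1
        trial_rows.append(f"NCT{nct:08d}\t{pki}\t{cancer}\t{phase}\t{year}\t{year + 2}")

    true_pairs = sorted(truth.true_pairs)
    phase_strings = {"I": "Phase 1", "II": "Phase 2", "III": "Phase 3", "IV": "Phase 4"}
    for pair in true_pairs:
        pk, cancer = pair
        pki = truth.pair_pki[pair]
        aff = float(rng.uniform(0.001, 0.029))
        act_rows.append(f"{pki}\t{pk}\t{aff:.6f}\t")
        # decoy supra-threshold activities never survive the affinity filter
        for _ in range(int(rng.integers(0, 3))):
            other = pks[int(rng.integers(0, len(pks)))]
            act_rows.append(f"{pki}\t{other}\t{float(rng.uniform(0.05, 1.0)):.6f}\t")
        y_iv = truth.pair_year[pair]
        trial(pki, cancer, phase_strings["IV"], y_iv)
        for _ in range(config.trials_per_true_pair - 1):
            phase = ("I", "II", "III")[int(rng.integers(0, 3))]
            year = int(max(config.year_range[0], y_iv - rng.integers(0, 3)))
            trial(pki, cancer, phase_strings[phase], year)

    for k in range(config.cap_exceeders):
        pki = f"PKIX{k + 1:02d}"
        chosen = rng.choice(len(pks), size=min(7, len(pks)), replace=False)
        for i in chosen:
            act_rows.append(f"{pki}\t{pks[i]}\t{float(rng.uniform(0.001, 0.029)):.6f}\t")

    n_decoys = config.pki_count - config.n_true_pairs - config.cap_exceeders
    for k in range(n_decoys):
        pki = f"PKID{k + 1:02d}"
        pk = pks[int(rng.integers(0, len(pks)))]
        act_rows.append(f"{pki}\t{pk}\t{float(rng.uniform(0.001, 0.029)):.6f}\t")
        for _ in range(2):
            cancer = cancers[int(rng.integers(0, len(cancers)))]
            if (pk, cancer) in truth.true_pairs:
                continue
            phase = ("I", "II")[int(rng.integers(0, 2))]
            year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
            trial(pki, cancer, phase_strings[phase], year)

    return "\n".join(act_rows) + "\n", "\n".join(trial_rows) + "\n"


# -- fixture on disk --------------------------------------------------------

def end_to_end_fixture(
    config: SynthConfig = SynthConfig(), out_dir: str | Path = "synth_fixture"
) -> dict[str, Path]:
    """Write all five input files plus the truth manifest into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    articles_tsv, annotations_tsv, truth = generate_corpus(config)
    activities_tsv, trials_tsv = generate_catalog_tables(config, truth)
    paths = {
        "articles": out_dir / "articles.tsv",
        "annotations": out_dir / "annotations.tsv",
        "mesh": out_dir / "mesh.jsonl",
        "activities": out_dir / "activities.tsv",
        "trials": out_dir / "trials.tsv",
        "truth": out_dir / "truth.json",
    }
    paths["articles"].write_text(articles_tsv, encoding="utf-8")
    paths["annotations"].write_text(annotations_tsv, encoding="utf-8")
    paths["mesh"].write_text(mesh_hierarchy_jsonl(config), encoding="utf-8")
    paths["activities"].write_text(activities_tsv, encoding="utf-8")
    paths["trials"].write_text(trials_tsv, encoding="utf-8")
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    return paths
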