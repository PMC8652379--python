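"""Corpus preparation: article filtering, concept replacement, tokenization.

Turns concept-annotated biomedical abstracts into token streams ready for
embedding.  The stages mirror a standard literature-mining preprocessing
pipeline:

1. Parse article records (TSV dialect or simplified PubMed-style XML).
2. Select relevant articles through a MeSH descriptor closure (an article
   qualifies if it carries a search descriptor or any descendant, or a
   keyword matching a label/synonym of one, and has a non-empty abstract).
3. Replace annotated concept spans (PubTator-style offsets) with single
   concept tokens so multi-word concepts such as "non-small-cell lung
   carcinoma" embed as one unit (``meshd002289``).
4. Normalize text: strip punctuation (splitting compounds), drop stop words
   and single letters while keeping uppercase acronyms, lemmatize, lowercase.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

__all__ = [
    "ArticleRecord",
    "ConceptAnnotation",
    "MeshHierarchy",
    "TokenDocument",
    "CorpusPrepError",
    "parse_articles",
    "parse_annotations",
    "select_relevant",
    "apply_concept_annotations",
    "preprocess_text",
    "concept_token",
    "load_stopwords",
    "lemmatize",
    "prepare_corpus",
    "write_corpus",
    "read_corpus",
]

ANNOTATION_CATEGORIES = {"chemical", "disease", "gene", "cellline", "snp", "species"}

#: NCBI taxon for Homo sapiens; annotations for it are deliberately skipped so
#: that words like "patient", "woman" or "boy" keep their own embeddings.
HUMAN_TAXON_ID = "9606"


class CorpusPrepError(ValueError):
    """Raised for malformed article, annotation or hierarchy inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArticleRecord:
    """One title+abstract with metadata; ``year`` is the earliest dated year."""

    pmid: str
    year: int
    mesh_ids: frozenset[str]
    keywords: frozenset[str]
    title: str
    abstract: str

    @property
    def annotated_text(self) -> str:
        """Title and abstract joined by a single space: the offset space."""
        return f"{self.title} {self.abstract}" if self.abstract else self.title


@dataclass(frozen=True)
class ConceptAnnotation:
    """A recognized concept span, 0-based half-open offsets into title+abstract."""

    pmid: str
    start: int
    end: int
    category: str
    concept_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusPrepError(
                f"pmid {self.pmid}: invalid annotation offsets [{self.start}, {self.end})"
            )
        if self.category not in ANNOTATION_CATEGORIES:
            raise CorpusPrepError(
                f"pmid {self.pmid}: unknown annotation category {self.category!r}"
            )


@dataclass
class MeshHierarchy:
    """Descriptor id -> {label, synonyms, parents}; acyclic by construction."""

    nodes: dict[str, dict]
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {}
        for node_id, node in self.nodes.items():
            for parent in node.get("parents", ()):
                self._children.setdefault(parent, set()).add(node_id)

    def closure(self, descriptor_ids: Iterable[str]) -> set[str]:
        """Return the ids plus every descendant (subcategory) of each id."""
        seen: set[str] = set()
        stack = [d for d in descriptor_ids]
        while stack:
            d = stack.pop()
            if d in seen:
                continue
            seen.add(d)
            stack.extend(self._children.get(d, ()))
        return seen

    def terms(self, descriptor_ids: Iterable[str]) -> set[str]:
        """Lowercased labels and synonyms of the given descriptors."""
        out: set[str] = set()
        for d in descriptor_ids:
            node = self.nodes.get(d)
            if node is None:
                continue
            if node.get("label"):
                out.add(node["label"].lower())
            out.update(s.lower() for s in node.get("synonyms", ()))
        return out

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "MeshHierarchy":
        nodes: dict[str, dict] = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    nodes[rec["id"]] = {
                        "label": rec.get("label", ""),
                        "synonyms": list(rec.get("synonyms", [])),
                        "parents": list(rec.get("parents", [])),
                    }
                except (json.JSONDecodeError, KeyError) as exc:
                    raise CorpusPrepError(f"mesh hierarchy line {lineno}: {exc}") from exc
        return cls(nodes)


@dataclass(frozen=True)
class TokenDocument:
    """An ordered stream of lowercase word/concept tokens for one article."""

    pmid: str
    tokens: tuple[str, ...]


# ---------------------------------------------------------------------------
# Parsing article records
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def parse_articles(source) -> list[ArticleRecord]:
    """Parse article records from a TSV table or simplified PubMed-style XML.

    The TSV dialect has six columns: pmid, year(s), mesh ids
    (semicolon-joined), keywords (semicolon-joined), title, abstract.  The
    year column may itself carry several semicolon-joined years (a record
    with multiple dated fields); the earliest is recorded.  XML input is
    detected by a leading ``<``.  A missing abstract yields an empty
    abstract field, never an error.
    """
    text = _source_text(source)
    if not text.strip():
        return []
    if text.lstrip().startswith("<"):
        return _parse_articles_xml(text)
    return _parse_articles_tsv(text)


def _source_text(source) -> str:
    if isinstance(source, Path) or (
        isinstance(source, str)
        and source
        and "\n" not in source
        and "\t" not in source
        and Path(source).is_file()
    ):
        with _open_text(source) as fh:
            return fh.read()
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _parse_articles_tsv(text: str) -> list[ArticleRecord]:
    records = []
    reader = csv.reader(io.StringIO(text), delimiter="\t", quoting=csv.QUOTE_NONE)
    for lineno, row in enumerate(reader, 1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if lineno == 1 and row[0].strip().lower() == "pmid":
            continue  # optional header
        if len(row) < 5:
            raise CorpusPrepError(f"line {lineno}: expected >=5 tab-separated fields, got {len(row)}")
        pmid = row[0].strip()
        if not pmid:
            raise CorpusPrepError(f"line {lineno}: empty pmid field")
        try:
            years = [int(y) for y in row[1].split(";") if y.strip()]
            if not years:
                raise ValueError("no year")
        except ValueError as exc:
            raise CorpusPrepError(f"pmid {pmid}: bad year field {row[1]!r}") from exc
        mesh = frozenset(m.strip() for m in row[2].split(";") if m.strip())
        keywords = frozenset(k.strip() for k in row[3].split(";") if k.strip())
        title = row[4].strip()
        abstract = row[5].strip() if len(row) > 5 else ""
        records.append(ArticleRecord(pmid, min(years), mesh, keywords, title, abstract))
    return records


def _parse_articles_xml(text: str) -> list[ArticleRecord]:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise CorpusPrepError(f"malformed XML: {exc}") from exc
    records = []
    for art in root.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            raise CorpusPrepError("PubmedArticle element without PMID")
        pmid = pmid_el.text.strip()
        years = []
        for year_el in art.iter("Year"):
            try:
                years.append(int(year_el.text))
            except (TypeError, ValueError) as exc:
                raise CorpusPrepError(f"pmid {pmid}: unparseable Year element") from exc
        if not years:
            raise CorpusPrepError(f"pmid {pmid}: no dated field")
        title_el = art.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        abstract = " ".join(
            "".join(el.itertext()).strip() for el in art.findall(".//AbstractText")
        ).strip()
        mesh = frozenset(
            el.get("UI").strip()
            for el in art.findall(".//MeshHeading/DescriptorName")
            if el.get("UI")
        )
        keywords = frozenset(
            "".join(el.itertext()).strip()
            for el in art.findall(".//Keyword")
            if "".join(el.itertext()).strip()
        )
        records.append(ArticleRecord(pmid, min(years), mesh, keywords, title, abstract))
    return records


def parse_annotations(source) -> list[ConceptAnnotation]:
    """Parse a PubTator-offset-style TSV: pmid, start, end, category, concept_id."""
    text = _source_text(source)
    anns = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        row = line.split("\t")
        if lineno == 1 and row[0].strip().lower() == "pmid":
            continue
        if len(row) != 5:
            raise CorpusPrepError(f"annotation line {lineno}: expected 5 fields, got {len(row)}")
        pmid, start, end, category, concept_id = (f.strip() for f in row)
        try:
            anns.append(ConceptAnnotation(pmid, int(start), int(end), category.lower(), concept_id))
        except ValueError as exc:
            raise CorpusPrepError(f"annotation line {lineno} (pmid {pmid}): {exc}") from exc
    return anns


# ---------------------------------------------------------------------------
# Relevance filtering
# ---------------------------------------------------------------------------

def select_relevant(
    articles: Sequence[ArticleRecord],
    search_ids: Iterable[str],
    hierarchy: MeshHierarchy,
) -> list[ArticleRecord]:
    """Keep articles matching the search descriptors or their subcategories.

    An article qualifies if its abstract is non-empty and it either carries a
    MeSH descriptor in the closure of ``search_ids`` or has a keyword that
    case-insensitively equals a label or synonym of a closure descriptor.
    Input order is preserved; unknown descriptors on articles are ignored.
    """
    search_ids = set(search_ids)
    missing = search_ids - set(hierarchy.nodes)
    if missing:
        raise CorpusPrepError(f"search descriptors not in hierarchy: {sorted(missing)}")
    closure = hierarchy.closure(search_ids)
    terms = hierarchy.terms(closure)
    out = []
    for art in articles:
        if not art.abstract:
            continue
        if art.mesh_ids & closure:
            out.append(art)
        elif any(k.lower() in terms for k in art.keywords):
            out.append(art)
    return out


# ---------------------------------------------------------------------------
# Concept replacement
# ---------------------------------------------------------------------------

_CATEGORY_PREFIX = {
    "chemical": "mesh",
    "disease": "mesh",
    "gene": "ncbigene",
    "species": "taxon",
    "cellline": "cvcl",
    "snp": "rs",
}
_ALNUM = re.compile(r"[^0-9a-z]")


def concept_token(category: str, concept_id: str) -> str:
    """Collision-free lowercase token for a concept id, e.g. ``meshd002289``.

    The category's namespace prefix is prepended unless the id already starts
    with it after normalization (``MESH:D002289`` -> ``meshd002289``;
    ``rs334`` stays ``rs334``; ``CVCL_0023`` -> ``cvcl0023``).
    """
    prefix = _CATEGORY_PREFIX[category]
    norm = _ALNUM.sub("", concept_id.lower())
    if not norm:
        raise CorpusPrepError(f"empty concept id {concept_id!r}")
    if not norm.startswith(prefix):
        norm = prefix + norm
    return norm


def _resolve_overlaps(anns: Sequence[ConceptAnnotation]) -> list[ConceptAnnotation]:
    # Longest span wins; ties by leftmost start, then lexicographic concept id.
    ordered = sorted(anns, key=lambda a: (-(a.end - a.start), a.start, a.concept_id))
    kept: list[ConceptAnnotation] = []
    for ann in ordered:
        if all(ann.end <= k.start or ann.start >= k.end for k in kept):
            kept.append(ann)
    return kept


def apply_concept_annotations(
    article: ArticleRecord, anns: Sequence[ConceptAnnotation]
) -> str:
    """Replace annotated spans of title+abstract with concept tokens.

    Human-species annotations (taxon 9606) are skipped so that gender- and
    age-bearing words survive.  Overlapping annotations are resolved to the
    longest span; replacement runs in descending start order so earlier
    offsets stay valid.  Characters outside annotated spans are untouched.
    """
    text = article.annotated_text
    relevant = [a for a in anns if a.pmid == article.pmid]
    for ann in relevant:
        if ann.end > len(text):
            raise CorpusPrepError(
                f"pmid {article.pmid}: annotation [{ann.start}, {ann.end}) exceeds "
                f"text length {len(text)}"
            )
    def _is_human(a: ConceptAnnotation) -> bool:
        norm = _ALNUM.sub("", a.concept_id.lower())
        return a.category == "species" and norm.removeprefix("taxon") == HUMAN_TAXON_ID

    kept = [a for a in _resolve_overlaps(relevant) if not _is_human(a)]
    for ann in sorted(kept, key=lambda a: -a.start):
        text = text[: ann.start] + concept_token(ann.category, ann.concept_id) + text[ann.end :]
    return text


# ---------------------------------------------------------------------------
# Text preprocessing: punctuation, stop words, lemmatization, lowercasing
# ---------------------------------------------------------------------------

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def load_stopwords() -> frozenset[str]:
    """The versioned stop list shipped with the package (lowercase entries)."""
    data = resources.files("kce.data").joinpath("stopwords.txt").read_text(encoding="utf-8")
    return frozenset(
        line.strip() for line in data.splitlines() if line.strip() and not line.startswith("#")
    )


# Dictionary lemmatizer: irregular forms plus safe plural suffix rules.  The
# contract is modest — plural nouns to singular, listed comparative/superlative
# adjectives to base — matching what a WordNet-style lemmatizer does on the
# vocabulary this pipeline actually meets.  Tokens containing digits (concept
# tokens) are never touched.
_LEMMA_EXCEPTIONS = {
    "higher": "high", "highest": "high",
    "lower": "low", "lowest": "low",
    "greater": "great", "greatest": "great",
    "larger": "large", "largest": "large",
    "smaller": "small", "smallest": "small",
    "older": "old", "oldest": "old",
    "younger": "young", "youngest": "young",
    "stronger": "strong", "strongest": "strong",
    "weaker": "weak", "weakest": "weak",
    "earlier": "early", "earliest": "early",
    "later": "late", "latest": "late",
    "better": "good", "best": "good",
    "worse": "bad", "worst": "bad",
    "mice": "mouse", "men": "man", "women": "woman", "children": "child",
    "feet": "foot", "teeth": "tooth",
    "analyses": "analysis", "diagnoses": "diagnosis", "prognoses": "prognosis",
    "metastases": "metastasis", "hypotheses": "hypothesis", "bases": "basis",
    "criteria": "criterion", "phenomena": "phenomenon", "data": "data",
    "carcinomata": "carcinoma",
}
_PLURAL_KEEP_S = ("ss", "us", "is")  # mass/class, virus, analysis-style endings


def lemmatize(token: str) -> str:
    """Reduce an inflected alphabetic token to its dictionary base form."""
    if not token.isalpha():
        return token
    low = token.lower()
    if low in _LEMMA_EXCEPTIONS:
        base = _LEMMA_EXCEPTIONS[low]
    elif low.endswith("ies") and len(low) > 4:
        base = low[:-3] + "y"
    elif low.endswith(("ches", "shes", "sses", "xes", "zes")) and len(low) > 4:
        base = low[:-2]
    elif low.endswith("s") and not low.endswith(_PLURAL_KEEP_S) and len(low) > 3:
        base = low[:-1]
    else:
        return token
    # Preserve the original casing class so acronym/stop-word logic already
    # applied upstream is not disturbed.
    if token.isupper():
        return base.upper()
    if token[0].isupper():
        return base.capitalize()
    return base


def _is_acronym(token: str) -> bool:
    return len(token) >= 2 and token.isupper() and token.isalpha()


def preprocess_text(text: str, stoplist: frozenset[str] | None = None) -> list[str]:
    """Normalize concept-replaced text into the final token stream.

    Order of stages: punctuation removal (compounds split), stop-word removal
    in lower/capitalized form (uppercase acronyms of length >=2 survive even
    when they coincide with stop words, e.g. ALL for acute lymphocytic
    leukemia), single-letter removal, lemmatization, lowercasing last.
    """
    if stoplist is None:
        stoplist = load_stopwords()
    tokens = text.translate(_PUNCT_TABLE).split()
    out = []
    for tok in tokens:
        if len(tok) < 2:
            continue
        if not _is_acronym(tok) and tok.lower() in stoplist:
            continue
        out.append(lemmatize(tok).lower())
    return out


# ---------------------------------------------------------------------------
# End-to-end corpus preparation and the corpus file format
# ---------------------------------------------------------------------------

def prepare_corpus(
    articles: Sequence[ArticleRecord],
    annotations: Sequence[ConceptAnnotation],
    hierarchy: MeshHierarchy,
    search_ids: Iterable[str],
    stoplist: frozenset[str] | None = None,
) -> list[TokenDocument]:
    """Filter, concept-replace and tokenize a full article set."""
    if stoplist is None:
        stoplist = load_stopwords()
    by_pmid: dict[str, list[ConceptAnnotation]] = {}
    for ann in annotations:
        by_pmid.setdefault(ann.pmid, []).append(ann)
    docs = []
    for art in select_relevant(articles, search_ids, hierarchy):
        replaced = apply_concept_annotations(art, by_pmid.get(art.pmid, []))
        tokens = preprocess_text(replaced, stoplist)
        if tokens:
            docs.append(TokenDocument(art.pmid, tuple(tokens)))
    return docs


def write_corpus(docs: Iterable[TokenDocument], path: str | Path) -> None:
    """One document per line: pmid followed by space-separated tokens."""
    with _open_text(path, "wt") as fh:
        for doc in docs:
            fh.write(doc.pmid + " " + " ".join(doc.tokens) + "\n")


def read_corpus(path: str | Path) -> list[TokenDocument]:
    docs = []
    with _open_text(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                docs.append(TokenDocument(parts[0], tuple(parts[1:])))
    return docs
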