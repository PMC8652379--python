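"""PKI target catalog and clinical-trial evidence for PK-cancer pairs.

Joins two evidence sources into (protein kinase, cancer) pairs:

* activity records (drug, kinase, affinity in uM) from a DrugCentral-style
  extract, filtered to affinities below 0.03 uM and at most the five
  strongest-bound kinases per inhibitor;
* clinical-trial records (NCT id, drug, cancer MeSH id, phase I-IV, years)
  from a ClinicalTrials.gov-style extract.

Each trial of inhibitor X against cancer C contributes evidence for every
pair (PK, C) with PK a retained target of X; phase IV is later treated as
evidence of therapeutic efficacy.
"""

from __future__ import annotations

import csv
import io
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ActivityRecord",
    "CatalogConfig",
    "TrialRecord",
    "PKCancerEvidence",
    "SkipReport",
    "parse_activities",
    "filter_activities",
    "parse_trials",
    "derive_pair_evidence",
    "target_map_summary",
    "Phase",
]

Phase = str  # one of "I", "II", "III", "IV"
PHASES = ("I", "II", "III", "IV")


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    """One measured drug-kinase activity (Ki, IC50, ...) in micromolar."""

    pki: str
    pk: str
    affinity_um: float
    pmid: str | None = None

    def __post_init__(self) -> None:
        if not (self.affinity_um > 0):
            raise CatalogError(
                f"activity for ({self.pki}, {self.pk}): affinity must be positive, "
                f"got {self.affinity_um}"
            )


@dataclass(frozen=True)
class CatalogConfig:
    """Affinity ceiling (uM) and per-inhibitor target cap."""

    affinity_max_um: float = 0.03
    n_pk: int = 5

    def __post_init__(self) -> None:
        if self.affinity_max_um <= 0:
            raise CatalogError("affinity_max_um must be positive")
        if self.n_pk < 1:
            raise CatalogError("n_pk must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    nct_id: str
    pki: str
    cancer: str  # MeSH descriptor id
    phase: Phase
    start_year: int
    completion_year: int | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise CatalogError(f"trial {self.nct_id}: phase must be one of {PHASES}")
        if self.completion_year is not None and self.start_year > self.completion_year:
            raise CatalogError(f"trial {self.nct_id}: start year after completion year")


@dataclass
class PKCancerEvidence:
    """A (PK, cancer) pair with its merged set of trial evidence."""

    pk: str
    cancer: str
    evidence: set[tuple[Phase, int, str, str]] = field(default_factory=set)
    # each item: (phase, start_year, nct_id, pki)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.pk, self.cancer)


@dataclass
class SkipReport:
    """Counts of rows dropped or ignored during parsing/joining, by reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def bump(self, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _read_table(source) -> list[list[str]]:
    if isinstance(source, Path) or (
        isinstance(source, str)
        and source
        and "\n" not in source
        and "\t" not in source
        and Path(source).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    reader = csv.reader(io.StringIO(text), delimiter="\t", quoting=csv.QUOTE_NONE)
    return [row for row in reader if row and any(f.strip() for f in row)]


def parse_activities(source) -> list[ActivityRecord]:
    """Activities TSV: pki, pk, affinity_um, pmid (pmid optional)."""
    records = []
    for lineno, row in enumerate(_read_table(source), 1):
        if lineno == 1 and row[0].strip().lower() in {"pki", "drug"}:
            continue
        if len(row) < 3:
            raise CatalogError(f"activities line {lineno}: expected >=3 fields")
        try:
            aff = float(row[2])
        except ValueError as exc:
            raise CatalogError(f"activities line {lineno}: bad affinity {row[2]!r}") from exc
        pmid = row[3].strip() if len(row) > 3 and row[3].strip() else None
        records.append(ActivityRecord(row[0].strip(), row[1].strip(), aff, pmid))
    return records


_PHASE_PATTERNS = [
    (re.compile(r"(?:phase[\s_]*)?(?:iv|4)\b", re.I), "IV"),
    (re.compile(r"(?:phase[\s_]*)?(?:iii|3)\b", re.I), "III"),
    (re.compile(r"(?:phase[\s_]*)?(?:ii|2)\b", re.I), "II"),
    (re.compile(r"(?:phase[\s_]*)?(?:i|1)\b", re.I), "I"),
]


def normalize_phase(raw: str) -> Phase:
    """Map free-form phase strings to the I-IV enum.

    Combined labels such as "Phase 1/Phase 2" normalize to the higher phase
    (conservative when phase IV is the positive-evidence criterion).
    """
    for pattern, phase in _PHASE_PATTERNS:
        if pattern.search(raw):
            return phase
    raise CatalogError(f"unparseable trial phase {raw!r}")


def parse_trials(
    source,
    cancer_lexicon: Iterable[str],
    pki_set: Iterable[str],
) -> tuple[list[TrialRecord], SkipReport]:
    """Trials TSV: nct_id, pki, cancer_mesh, phase, start_year, completion_year.

    Rows with a cancer outside the lexicon or an inhibitor outside
    ``pki_set`` are dropped; rows with an unparseable phase or year are
    collected in the skip report rather than aborting the parse.
    """
    cancer_lexicon = set(cancer_lexicon)
    pki_set = set(pki_set)
    trials: list[TrialRecord] = []
    report = SkipReport()
    for lineno, row in enumerate(_read_table(source), 1):
        if lineno == 1 and row[0].strip().lower() in {"nct_id", "nct"}:
            continue
        if len(row) < 5:
            report.bump("short_row")
            continue
        nct, pki, cancer = row[0].strip(), row[1].strip(), row[2].strip()
        if cancer not in cancer_lexicon:
            report.bump("cancer_not_in_lexicon")
            continue
        if pki not in pki_set:
            report.bump("unknown_pki")
            continue
        try:
            phase = normalize_phase(row[3])
        except CatalogError:
            report.bump("bad_phase")
            continue
        try:
            start = int(row[4])
            completion = int(row[5]) if len(row) > 5 and row[5].strip() else None
        except ValueError:
            report.bump("bad_year")
            continue
        try:
            trials.append(TrialRecord(nct, pki, cancer, phase, start, completion))
        except CatalogError:
            report.bump("invalid_record")
    return trials, report


# ---------------------------------------------------------------------------
# Target-map construction and the evidence join
# ---------------------------------------------------------------------------

def filter_activities(
    records: Sequence[ActivityRecord], config: CatalogConfig = CatalogConfig()
) -> dict[str, list[str]]:
    """Per-inhibitor ordered target list after affinity and top-n filtering.

    For each (pki, pk) the minimum (most potent) affinity is kept; pairs at
    or above ``affinity_max_um`` are dropped; each inhibitor retains at most
    ``n_pk`` kinases, the lowest-affinity ones ("top" = strongest binding),
    ordered by ascending affinity with ties broken by kinase symbol.
    """
    best: dict[tuple[str, str], float] = {}
    for rec in records:
        key = (rec.pki, rec.pk)
        if key not in best or rec.affinity_um < best[key]:
            best[key] = rec.affinity_um
    by_pki: dict[str, list[tuple[float, str]]] = {}
    for (pki, pk), aff in best.items():
        if aff < config.affinity_max_um:
            by_pki.setdefault(pki, []).append((aff, pk))
    return {
        pki: [pk for _, pk in sorted(pairs)[: config.n_pk]]
        for pki, pairs in sorted(by_pki.items())
    }


def derive_pair_evidence(
    trials: Sequence[TrialRecord],
    target_map: Mapping[str, Sequence[str]],
) -> tuple[list[PKCancerEvidence], SkipReport]:
    """Join trials with inhibitor targets into merged PK-cancer evidence.

    Every trial of inhibitor X against cancer C yields an evidence item
    (phase, start_year, nct, X) on the pair (PK, C) for each PK targeted by
    X; items for the same pair merge across trials.  Trials whose inhibitor
    has no retained targets are counted in the skip report.
    """
    report = SkipReport()
    pairs: dict[tuple[str, str], PKCancerEvidence] = {}
    for trial in trials:
        targets = target_map.get(trial.pki, ())
        if not targets:
            report.bump("pki_without_targets")
            continue
        for pk in targets:
            ev = pairs.setdefault((pk, trial.cancer), PKCancerEvidence(pk, trial.cancer))
            ev.evidence.add((trial.phase, trial.start_year, trial.nct_id, trial.pki))
    return [pairs[k] for k in sorted(pairs)], report


def target_map_summary(target_map: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Summary statistics of a target map: the numbers a catalog report prints.

    Counts inhibitors, distinct kinases and (pki, pk) pairs, plus the
    mean/median/min/max number of kinases per inhibitor and inhibitors per
    kinase.
    """
    per_pki = [len(v) for v in target_map.values()]
    pkis_per_pk: dict[str, int] = {}
    for pks in target_map.values():
        for pk in pks:
            pkis_per_pk[pk] = pkis_per_pk.get(pk, 0) + 1
    per_pk = list(pkis_per_pk.values())
    if not per_pki:
        return {"n_pkis": 0, "n_pks": 0, "n_pairs": 0}
    return {
        "n_pkis": len(target_map),
        "n_pks": len(pkis_per_pk),
        "n_pairs": sum(per_pki),
        "pks_per_pki_mean": statistics.mean(per_pki),
        "pks_per_pki_median": statistics.median(per_pki),
        "pks_per_pki_min": min(per_pki),
        "pks_per_pki_max": max(per_pki),
        "pkis_per_pk_mean": statistics.mean(per_pk),
        "pkis_per_pk_median": statistics.median(per_pk),
        "pkis_per_pk_min": min(per_pk),
        "pkis_per_pk_max": max(per_pk),
    }
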