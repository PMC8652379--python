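"""Historical training/test splits and the de-novo prediction universe.

The validation protocol fixes a target year, trains on the past and tests on
the future:

* positive training pairs — (PK, cancer) pairs with at least one phase-IV
  trial starting no later than the target year (only phase IV is ever used
  for training);
* negative training pairs — a uniform sample, ten times the positive count,
  of pairs with no trial evidence up to the target year;
* positive test pairs — pairs whose first qualifying trial (all phases, or
  phase IV only) starts inside the test window, that have no any-phase
  evidence through the target year, and that are not in a caller-supplied
  exclusion set built from the unfiltered drug-target associations;
* negative test pairs — sampled disjointly from every evidence pair and
  from both training sets.

The de-novo universe is the full PK x cancer grid minus any-phase evidence
pairs; kinases never yet targeted by an inhibitor remain in the universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .catalog import PKCancerEvidence, Phase

__all__ = [
    "SplitConfig",
    "DatasetSplit",
    "SplitError",
    "build_positive_train",
    "sample_negative_set",
    "build_test_sets",
    "build_prediction_universe",
    "build_split",
]

Pair = tuple[str, str]


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitConfig:
    target_year: int
    test_window: tuple[int, int]
    neg_ratio: int = 10
    test_phase_filter: str = "all_phases"  # or "phase_iv_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neg_ratio < 1:
            raise SplitError("neg_ratio must be >= 1")
        first, last = self.test_window
        if first <= self.target_year:
            raise SplitError("test window must start after the target year")
        if first > last:
            raise SplitError("empty test window")
        if self.test_phase_filter not in {"all_phases", "phase_iv_only"}:
            raise SplitError(f"unknown test_phase_filter {self.test_phase_filter!r}")


@dataclass
class DatasetSplit:
    positives_train: set[Pair]
    negatives_train: set[Pair]
    positives_test: set[Pair]
    negatives_test: set[Pair]
    universe: set[Pair]
    config: SplitConfig | None = None

    def labeled(self, role: str) -> list[tuple[str, str, int]]:
        pos = self.positives_train if role == "train" else self.positives_test
        neg = self.negatives_train if role == "train" else self.negatives_test
        return [(pk, c, 1) for pk, c in sorted(pos)] + [(pk, c, 0) for pk, c in sorted(neg)]

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = {
            "positives_train": self.positives_train,
            "negatives_train": self.negatives_train,
            "positives_test": self.positives_test,
            "negatives_test": self.negatives_test,
        }
        for name, pairs in names.items():
            label = "1" if name.startswith("pos") else "0"
            role = "train" if name.endswith("train") else "test"
            with open(out_dir / f"{name}.tsv", "w", encoding="utf-8") as fh:
                fh.write("pk\tcancer\tlabel\trole\n")
                for pk, cancer in sorted(pairs):
                    fh.write(f"{pk}\t{cancer}\t{label}\t{role}\n")
        manifest = {
            "counts": {k: len(v) for k, v in names.items()},
            "universe_size": len(self.universe),
        }
        if self.config is not None:
            manifest["config"] = {
                "target_year": self.config.target_year,
                "test_window": list(self.config.test_window),
                "neg_ratio": self.config.neg_ratio,
                "test_phase_filter": self.config.test_phase_filter,
                "seed": self.config.seed,
            }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Evidence predicates
# ---------------------------------------------------------------------------

def _evidence_years(
    evidence: Sequence[PKCancerEvidence], phases: Iterable[Phase] | None = None
) -> dict[Pair, int]:
    """First (minimum) start year of qualifying evidence per pair."""
    phases = set(phases) if phases is not None else None
    years: dict[Pair, int] = {}
    for ev in evidence:
        for phase, year, _nct, _pki in ev.evidence:
            if phases is not None and phase not in phases:
                continue
            if ev.pair not in years or year < years[ev.pair]:
                years[ev.pair] = year
    return years


def build_positive_train(
    evidence: Sequence[PKCancerEvidence], config: SplitConfig
) -> set[Pair]:
    """Pairs with phase-IV evidence starting no later than the target year."""
    first_iv = _evidence_years(evidence, phases={"IV"})
    return {pair for pair, year in first_iv.items() if year <= config.target_year}


def sample_negative_set(
    universe: Iterable[Pair], excluded: Iterable[Pair], size: int, seed: int
) -> set[Pair]:
    """Uniform sample without replacement from universe minus excluded."""
    candidates = sorted(set(universe) - set(excluded))
    if len(candidates) < size:
        raise SplitError(
            f"cannot sample {size} negatives from {len(candidates)} candidates "
            f"(short by {size - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=size, replace=False)
    return {candidates[i] for i in chosen}


def build_test_sets(
    evidence: Sequence[PKCancerEvidence],
    drug_pairs_any_affinity: Iterable[Pair],
    split_so_far: DatasetSplit,
    config: SplitConfig,
) -> tuple[set[Pair], set[Pair]]:
    """Positive and negative test pairs for the test window.

    ``drug_pairs_any_affinity`` is the exclusion set of pairs derivable from
    ANY drug-kinase association (no affinity or top-n filter) with evidence
    through the target year.  Test positives must first qualify inside the
    window, have no any-phase evidence up to the target year, and avoid the
    exclusion set.  Test negatives are disjoint from every evidence pair and
    from both training sets.
    """
    phases = None if config.test_phase_filter == "all_phases" else {"IV"}
    first_qual = _evidence_years(evidence, phases=phases)
    first_any = _evidence_years(evidence, phases=None)
    exclusion = set(drug_pairs_any_affinity)
    lo, hi = config.test_window
    positives = {
        pair
        for pair, year in first_qual.items()
        if lo <= year <= hi
        and first_any[pair] > config.target_year
        and pair not in exclusion
        # a pair already drawn blind as a training negative is not re-admitted,
        # keeping the four split sets pairwise disjoint
        and pair not in split_so_far.negatives_train
        and pair not in split_so_far.positives_train
    }
    all_evidence_pairs = set(first_any)
    excluded = (
        all_evidence_pairs
        | exclusion
        | split_so_far.positives_train
        | split_so_far.negatives_train
        | positives
    )
    negatives = sample_negative_set(
        split_so_far.universe, excluded, config.neg_ratio * len(positives), config.seed + 1
    ) if positives else set()
    return positives, negatives


def build_prediction_universe(
    all_pks: Iterable[str],
    all_cancers: Iterable[str],
    evidence: Sequence[PKCancerEvidence],
) -> set[Pair]:
    """Full PK x cancer grid minus pairs with evidence in any phase.

    A kinase absent from every activity record (never targeted) still pairs
    with every cancer: untargeted kinases are exactly the interesting
    de-novo candidates.
    """
    grid = {(pk, c) for pk in all_pks for c in all_cancers}
    return grid - {ev.pair for ev in evidence}


def build_split(
    evidence: Sequence[PKCancerEvidence],
    all_pks: Iterable[str],
    all_cancers: Iterable[str],
    config: SplitConfig,
    drug_pairs_any_affinity: Iterable[Pair] = (),
) -> DatasetSplit:
    """Assemble a full labeled split under the historical protocol."""
    all_pks, all_cancers = sorted(set(all_pks)), sorted(set(all_cancers))
    universe = {(pk, c) for pk in all_pks for c in all_cancers}
    positives_train = build_positive_train(evidence, config)
    if not positives_train:
        raise SplitError(f"no phase-IV evidence up to target year {config.target_year}")
    evidence_by_target_year = {
        pair
        for pair, year in _evidence_years(evidence).items()
        if year <= config.target_year
    }
    negatives_train = sample_negative_set(
        universe,
        evidence_by_target_year | positives_train,
        config.neg_ratio * len(positives_train),
        config.seed,
    )
    split = DatasetSplit(
        positives_train=positives_train,
        negatives_train=negatives_train,
        positives_test=set(),
        negatives_test=set(),
        universe=universe,
        config=config,
    )
    positives_test, negatives_test = build_test_sets(
        evidence, drug_pairs_any_affinity, split, config
    )
    split.positives_test = positives_test
    split.negatives_test = negatives_test
    return split
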