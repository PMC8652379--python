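"""End-to-end orchestration: corpus -> embeddings -> evidence -> prediction.

Glue that runs the full method on a fixture directory (as written by
``synth.end_to_end_fixture`` or assembled from real extracts): prepare the
token corpus, train skip-gram embeddings, build the inhibitor target map and
trial evidence, construct the historical split, train and evaluate the
difference-vector random forest, run the co-occurrence baseline, and rank
the de-novo prediction universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from . import baseline as baseline_mod
from . import catalog, classifier, corpus_prep, embedding, splits
from .synth import SEARCH_ROOT_CANCER, SEARCH_ROOT_KINASE

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    corpus: list
    embedding_model: embedding.EmbeddingModel
    target_map: dict
    evidence: list
    split: splits.DatasetSplit
    model: object
    report: classifier.EvaluationReport
    permutation_auroc: float
    baseline_rows: list
    baseline_best_k: int
    baseline_max_f1: float
    predictions: list


def run_pipeline(
    fixture: Mapping[str, Path],
    pk_tokens: Mapping[str, str],
    cancer_tokens: Mapping[str, str],
    split_config: splits.SplitConfig,
    embed_config: embedding.EmbeddingConfig | None = None,
    catalog_config: catalog.CatalogConfig = catalog.CatalogConfig(),
    search_space: classifier.SearchSpace | None = None,
    search_ids: tuple[str, ...] = (SEARCH_ROOT_CANCER, SEARCH_ROOT_KINASE),
    baseline_config: baseline_mod.BaselineConfig = baseline_mod.BaselineConfig(),
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on the input files named in ``fixture``.

    ``fixture`` maps the keys articles/annotations/mesh/activities/trials to
    file paths.  ``pk_tokens`` / ``cancer_tokens`` translate kinase symbols
    and cancer MeSH ids to corpus concept tokens.  ``seed`` drives embedding
    initialization, hyperparameter search and the permutation control;
    negative sampling uses the split config's own seed.
    """
    if embed_config is None:
        embed_config = embedding.EmbeddingConfig(seed=seed)
    if search_space is None:
        # fixture-scale search: same axes as the full space, trimmed so the
        # whole run stays in the few-minute range on one CPU
        search_space = classifier.SearchSpace(
            n_estimators=(100, 200, 300), iterations=20, seed=seed
        )

    # 1. corpus preparation
    articles = corpus_prep.parse_articles(fixture["articles"])
    annotations = corpus_prep.parse_annotations(fixture["annotations"])
    hierarchy = corpus_prep.MeshHierarchy.from_jsonl(fixture["mesh"])
    corpus = corpus_prep.prepare_corpus(articles, annotations, hierarchy, search_ids)
    logger.info("prepared corpus: %d documents", len(corpus))

    # 2. embeddings
    model_emb = embedding.train_skipgram(corpus, embed_config)
    logger.info("trained embeddings: %d tokens x %d dims", len(model_emb.vocabulary), model_emb.dim)

    # 3. catalog
    activities = catalog.parse_activities(fixture["activities"])
    target_map = catalog.filter_activities(activities, catalog_config)
    unfiltered_map = catalog.filter_activities(
        activities, catalog.CatalogConfig(affinity_max_um=1e9, n_pk=10**6)
    )
    trials, _skip = catalog.parse_trials(
        fixture["trials"], cancer_lexicon=cancer_tokens.keys(), pki_set={r.pki for r in activities}
    )
    evidence, _skip2 = catalog.derive_pair_evidence(trials, target_map)
    evidence_any, _ = catalog.derive_pair_evidence(trials, unfiltered_map)
    exclusion = {
        ev.pair
        for ev in evidence_any
        if any(year <= split_config.target_year for _, year, _, _ in ev.evidence)
    }

    # 4. historical split over the embeddable grid
    embeddable_pks = sorted(pk for pk, t in pk_tokens.items() if t in model_emb)
    embeddable_cancers = sorted(c for c, t in cancer_tokens.items() if t in model_emb)
    split = splits.build_split(
        evidence, embeddable_pks, embeddable_cancers, split_config,
        drug_pairs_any_affinity=exclusion,
    )

    # 5. difference-vector random forest
    def rows_for(pos, neg):
        labels = {p: 1 for p in pos} | {p: 0 for p in neg}
        return classifier.build_difference_features(
            sorted(labels), model_emb, pk_tokens, cancer_tokens, labels=labels
        )

    train_rows = rows_for(split.positives_train, split.negatives_train)
    test_rows = rows_for(split.positives_test, split.negatives_test)
    model = classifier.train_classifier(train_rows, search_space)
    scores = classifier.score_pairs(model, test_rows)
    test_labels = [r.label for r in test_rows]
    report = classifier.evaluate(scores, test_labels)
    perm_auroc = classifier.permutation_control_auroc(scores, test_labels, seed=seed)

    # 6. co-occurrence baseline on the same test pairs
    counts = baseline_mod.count_cooccurrence(corpus, pk_tokens, cancer_tokens)
    b_rows, b_best_k, b_max_f1 = baseline_mod.baseline_sweep(
        counts, split.positives_test, split.negatives_test, baseline_config
    )

    # 7. de-novo universe ranking
    universe = splits.build_prediction_universe(embeddable_pks, embeddable_cancers, evidence)
    universe_rows = classifier.build_difference_features(
        sorted(universe), model_emb, pk_tokens, cancer_tokens
    )
    predictions = classifier.rank_predictions(model, universe_rows, report.thresholds["gmean"])

    return PipelineResult(
        corpus=corpus,
        embedding_model=model_emb,
        target_map=target_map,
        evidence=evidence,
        split=split,
        model=model,
        report=report,
        permutation_auroc=perm_auroc,
        baseline_rows=b_rows,
        baseline_best_k=b_best_k,
        baseline_max_f1=b_max_f1,
        predictions=predictions,
    )
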