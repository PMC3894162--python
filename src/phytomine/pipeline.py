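"""End-to-end orchestration: simulate -> tag -> train -> extract ->
associate -> enrich -> infer -> network, with a JSON summary per stage.

The pipeline runs three corpora over one simulated world: a training corpus
whose candidates (labelled from the planted truth) train the two Naïve Bayes
models, a held-out evaluation corpus for external accuracy/F1, and a survey
corpus covering every planted truth edge, so the downstream association
stage sees the full planted enrichment structure.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import association_stats, chemo_inference, reporting
from .corpus_synthesis import (CorpusConfig, generate_corpus,
                               generate_eval_corpus, generate_survey_corpus)
from .entity_tagging import tag_abstract
from .relation_classifier import (evaluate, extract_relations,
                                  label_candidates, rank_features_tfidf,
                                  select_features_incremental,
                                  train_naive_bayes)

__all__ = ["PipelineConfig", "run_all", "train_task_model"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full pipeline around the corpus study conditions."""

    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    window: int = 10
    smoothing: float = 1.0
    patience: int = 5
    tolerance: float = 0.0
    shuffle_seed: int = 42
    max_features: int = 60
    q: float = 0.05
    tanimoto_threshold: float = 0.85
    min_support: int = 5
    top_k: int = 5
    n_eval_per_relation: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        corpus_raw = raw.pop("corpus", {})
        if "taxonomy_shape" in corpus_raw:
            corpus_raw["taxonomy_shape"] = tuple(corpus_raw["taxonomy_shape"])
        if "year_range" in corpus_raw:
            corpus_raw["year_range"] = tuple(corpus_raw["year_range"])
        return cls(corpus=CorpusConfig(**corpus_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["corpus"]["taxonomy_shape"] = list(d["corpus"]["taxonomy_shape"])
        d["corpus"]["year_range"] = list(d["corpus"]["year_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def train_task_model(tagged_corpus, task: str, cfg: PipelineConfig):
    """Rank features, select a working set by LOOCV plateau, train the model.

    Returns (model, selected_features, accuracy_trace, loocv_accuracy).
    """
    labelled = []
    for t in tagged_corpus:
        labelled.extend(label_candidates(t, task, cfg.window))
    labelled = [lc for lc in labelled if lc[1]]
    ranking = rank_features_tfidf(labelled)
    features, trace = select_features_incremental(
        labelled, ranking, patience=cfg.patience, tolerance=cfg.tolerance,
        smoothing=cfg.smoothing, shuffle_seed=cfg.shuffle_seed,
        max_features=cfg.max_features)
    model = train_naive_bayes(labelled, features, cfg.smoothing)
    return model, features, trace, trace[len(features) - 1]


def run_all(cfg: PipelineConfig, seed: int = 0,
            outdir: str | Path | None = None) -> dict:
    """Run every stage on one simulated world; return the summary dict.

    When ``outdir`` is given, stage outputs (bundle files, models, edges,
    association/enrichment tables, network exports, summary JSON) are
    written there.
    """
    from . import io as pio

    rng = random.Random(seed)
    bundle = generate_corpus(cfg.corpus, seed=rng.randrange(2 ** 31))
    eval_corpus = generate_eval_corpus(bundle, cfg.n_eval_per_relation,
                                       seed=rng.randrange(2 ** 31))
    survey = generate_survey_corpus(bundle, seed=rng.randrange(2 ** 31))

    dicts = list(bundle.dictionaries.values())
    tagged_train = [tag_abstract(a, dicts) for a in bundle.corpus]
    tagged_eval = [tag_abstract(a, dicts) for a in eval_corpus]
    tagged_survey = [tag_abstract(a, dicts) for a in survey]

    # --- classifiers ------------------------------------------------------
    model_content, feats_c, trace_c, loocv_c = train_task_model(
        tagged_train, "content", cfg)
    model_disease, feats_d, trace_d, loocv_d = train_task_model(
        tagged_train, "disease", cfg)

    eval_content = []
    eval_disease = []
    for t in tagged_eval:
        eval_content.extend(label_candidates(t, "content", cfg.window))
        eval_disease.extend(label_candidates(t, "disease", cfg.window))
    eval_content = [lc for lc in eval_content if lc[1]]
    eval_disease = [lc for lc in eval_disease if lc[1]]
    res_content = evaluate(model_content, eval_content, "related")
    res_disease = evaluate(model_disease, eval_disease, "preventive")

    # --- corpus-wide extraction ------------------------------------------
    content_edges, signed_edges = extract_relations(
        tagged_survey, model_content, model_disease, cfg.window)

    extracted = {(e.plant_id, e.compound_id, e.abstract_id)
                 for e in content_edges}
    extracted |= {(e.plant_id, e.disease_id, e.abstract_id)
                  for e in signed_edges}
    truth = {(x, y, a.abstract_id) for a in survey
             for (x, y, r) in a.truth if r != "none"}
    recall = len(extracted & truth) / len(truth) if truth else 1.0
    precision = len(extracted & truth) / len(extracted) if extracted else 1.0

    # --- association statistics ------------------------------------------
    associations = association_stats.associate_compounds_to_diseases(
        content_edges, signed_edges, q=cfg.q)
    significant = [r for r in associations if r.significant]
    planted = {(c, d, direction)
               for (c, d, direction) in bundle.truth_associations}
    recovered = {(r.compound_id, r.disease_id, r.direction)
                 for r in significant} & planted

    projected = association_stats.project_taxonomy_content(bundle.taxonomy)
    enrichment = association_stats.taxonomy_enrichment_all(projected, q=cfg.q)
    enriched_nodes = {(r.compound_id, r.node_id)
                      for r in enrichment if r.significant}

    # --- chemoinformatics -------------------------------------------------
    molecules = [chemo_inference.make_molecule(cid, smi)
                 for cid, smi in sorted(bundle.structures.items())]
    tested, similar, unexplored = chemo_inference.partition_phytochemicals(
        molecules, bundle.activity, cfg.tanimoto_threshold)
    confirmed, tested_assoc, fraction = chemo_inference.validate_predictions(
        associations, molecules, bundle.activity, bundle.target_disease)
    overlay = None
    if bundle.pathway:
        focus = sorted(bundle.pathway)[0]
        overlay = chemo_inference.pathway_overlay(
            focus, bundle.pathway[focus], associations, molecules,
            bundle.activity, cfg.tanimoto_threshold)

    # --- network and trends ----------------------------------------------
    network = reporting.build_network(
        signed_edges, min_support=cfg.min_support, top_k=cfg.top_k,
        edible=bundle.edible)

    summary = {
        "seed": seed,
        "world": {
            "n_plants": cfg.corpus.n_plants,
            "n_compounds": cfg.corpus.n_compounds,
            "n_diseases": cfg.corpus.n_diseases,
            "n_abstracts_train": len(bundle.corpus),
            "n_abstracts_eval": len(eval_corpus),
            "n_abstracts_survey": len(survey),
        },
        "content_classifier": {
            "n_features": len(feats_c), "loocv_accuracy": loocv_c,
            "accuracy": res_content.accuracy, "f1": res_content.f1,
            "n_eval": res_content.n,
        },
        "disease_classifier": {
            "n_features": len(feats_d), "loocv_accuracy": loocv_d,
            "accuracy": res_disease.accuracy, "f1": res_disease.f1,
            "n_eval": res_disease.n,
        },
        "extraction": {
            "n_content_edges": len(content_edges),
            "n_signed_edges": len(signed_edges),
            "recall": recall, "precision": precision,
        },
        "association": {
            "n_tested": len(associations),
            "n_significant": len(significant),
            "n_planted": len(planted),
            "n_planted_recovered": len(recovered),
        },
        "enrichment": {
            "n_tested": len(enrichment),
            "n_significant": len(enriched_nodes),
        },
        "chemoinformatics": {
            "n_tested": len(tested), "n_similar": len(similar),
            "n_unexplored": len(unexplored),
            "validation_confirmed": confirmed,
            "validation_tested": tested_assoc,
            "validation_fraction": fraction,
            "pathway_experimental": len(overlay["experimental"])
            if overlay else 0,
            "pathway_predicted": len(overlay["predicted"])
            if overlay else 0,
        },
        "network": {
            "n_edges": len(network.edges),
            "n_foods": len(network.foods()),
            "n_diseases": len(network.diseases()),
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_bundle(bundle, outdir / "bundle")
        (outdir / "model_content.json").write_text(model_content.to_json())
        (outdir / "model_disease.json").write_text(model_disease.to_json())
        pio.write_tagged_corpus(tagged_survey, outdir / "tagged_survey.jsonl")
        pio.write_edges(content_edges, signed_edges,
                        outdir / "edges_content.tsv",
                        outdir / "edges_disease.tsv")
        pio.write_associations(associations, outdir / "associations.tsv")
        pio.write_enrichment(enrichment, outdir / "enrichment.tsv")
        reporting.export_network(network, "graphml", outdir / "network.graphml")
        reporting.export_network(network, "sif", outdir / "network.sif")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
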