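"""End-to-end orchestration over a synthetic or real data bundle.

Chains the stages in their natural order: load alignment and genomes,
realign missing exons, compute conservation features, train the site
classifiers, label sites, and aggregate to transcripts and introns.  Each
stage is a plain call into the corresponding module; this file adds no logic
of its own beyond wiring and bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from splicecons import classify, conserve, realign
from splicecons.annotation import SiteIndex, extract_sites
from splicecons.genome_align_io import ExonSet, Genome, RefAlignment, load_maf
from splicecons.simdata import SimWorld


@dataclass
class PipelineResult:
    aln: RefAlignment
    aln_merged: RefAlignment
    candidates: list
    baselines: dict
    exons: ExonSet
    mane_index: SiteIndex
    catalog_index: SiteIndex
    random_index: SiteIndex
    scorer: conserve.ConservationScorer
    models: dict  # (site kind, model kind) -> model
    evaluations: dict
    labels: dict  # site key -> SiteLabel
    feature_X: dict  # group name -> matrix
    feature_keys: dict


def run_world_analysis(
    world: SimWorld,
    seed: int = 0,
    use_recovered_alignment: bool = True,
    train_kinds: tuple[str, ...] = ("full", "dinuc"),
) -> PipelineResult:
    """Run realignment, conservation scoring, training and labelling."""
    contig = world.config.contig
    aln = load_maf(world.paths["maf"], "ref")
    reference = world.reference
    targets = world.target_names

    chr1 = lambda txs: [t for t in txs if t.contig == contig]
    exons = ExonSet.from_transcripts(chr1(world.catalog_transcripts))
    candidates, baselines = realign.realign_missing_exons(
        aln, exons, reference, world.target_genomes, targets
    )
    merged = realign.merge_alignment(aln, candidates)
    use_aln = merged if use_recovered_alignment else aln

    mane_index = extract_sites(chr1(world.mane_transcripts), reference)
    catalog_index = extract_sites(chr1(world.catalog_transcripts), reference)
    random_index = extract_sites(world.random_transcripts, reference)

    scorer = conserve.ConservationScorer(
        use_aln, reference, world.target_genomes, targets
    )

    feature_X, feature_keys = {}, {}
    for name, sites in (
        ("mane_donor", list(mane_index.donors.values())),
        ("mane_acceptor", list(mane_index.acceptors.values())),
        ("random_donor", list(random_index.donors.values())),
        ("random_acceptor", list(random_index.acceptors.values())),
        ("catalog_donor", list(catalog_index.donors.values())),
        ("catalog_acceptor", list(catalog_index.acceptors.values())),
    ):
        X, keys = scorer.feature_matrix(sites)
        feature_X[name] = X
        feature_keys[name] = keys

    models, evaluations, labels = {}, {}, {}
    for site_kind in ("donor", "acceptor"):
        pos = feature_X[f"mane_{site_kind}"]
        neg = feature_X[f"random_{site_kind}"]
        for kind in train_kinds:
            model, ev = classify.train_classifier(pos, neg, kind=kind, seed=seed)
            models[(site_kind, kind)] = model
            evaluations[(site_kind, kind)] = ev
        model = models[(site_kind, train_kinds[0])]
        labels.update(
            classify.label_sites(
                model,
                feature_X[f"catalog_{site_kind}"],
                feature_keys[f"catalog_{site_kind}"],
            )
        )
        labels.update(
            classify.label_sites(
                model,
                feature_X[f"random_{site_kind}"],
                feature_keys[f"random_{site_kind}"],
            )
        )
    return PipelineResult(
        aln=aln,
        aln_merged=merged,
        candidates=candidates,
        baselines=baselines,
        exons=exons,
        mane_index=mane_index,
        catalog_index=catalog_index,
        random_index=random_index,
        scorer=scorer,
        models=models,
        evaluations=evaluations,
        labels=labels,
        feature_X=feature_X,
        feature_keys=feature_keys,
    )
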