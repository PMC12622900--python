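"""End-to-end driver: simulate -> expression -> score -> network -> cluster.

Runs the whole analysis on a synthetic study and writes every exchange
format (TSV spot table / design / annotation, expression matrix, fold
changes, GO score table, per-aspect GraphML networks and edge lists,
Newick dendrogram and merge table). All randomness derives from the
simulation seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import clustering, cooccurrence, expression, go_scoring, simulate

log = logging.getLogger(__name__)


def run_study(cfg: simulate.SimConfig, outdir: str | Path,
              normalize_method: str = "median-scale",
              up: float = 2.0, down: float = 0.5, k: int = 3,
              singleton_aspects: tuple[str, ...] = ("BP",),
              universe: str = "all",
              layout_seed: int | None = None,
              write_figures: bool = False) -> dict:
    """Run the full synthetic study and write all outputs to ``outdir``.

    Returns a dict with the in-memory results (annotation, matrices,
    scores, networks, dendrogram) and the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if layout_seed is None:
        layout_seed = cfg.seed

    ann = simulate.simulate_annotation(cfg)
    spots, meta, truth = simulate.simulate_experiment(cfg, ann)
    expression.write_spot_table(spots, outdir / "spots.tsv")
    meta.to_csv(outdir / "design.tsv", sep="\t", index=False)
    ann.to_tsv(outdir / "annotation.tsv")
    truth.multipliers.to_csv(outdir / "ground_truth.tsv", sep="\t")

    matrix = expression.average_spots(spots, meta)
    matrix = expression.normalize(matrix, method=normalize_method)
    matrix.to_tsv(outdir / "expression_matrix.tsv")
    fc = expression.fold_change(matrix)
    fc.to_tsv(outdir / "fold_change.tsv")

    scores = go_scoring.score_terms(fc, ann)
    scores = go_scoring.classify_terms(scores, up=up, down=down)
    go_scoring.write_score_table(scores, outdir / "go_scores.tsv")

    networks = {}
    for aspect in go_scoring.ASPECTS:
        net = cooccurrence.build_network(ann, scores=scores, k=k,
                                         aspect=aspect, universe=universe,
                                         fc=fc)
        if aspect in singleton_aspects:
            main, single = cooccurrence.split_singletons(net, aspects=None)
            cooccurrence.export_graph(main, outdir, f"network_{aspect}_main",
                                      layout_seed=layout_seed,
                                      image=write_figures)
            cooccurrence.export_graph(single, outdir,
                                      f"network_{aspect}_singleton",
                                      layout_seed=layout_seed,
                                      image=write_figures)
            networks[aspect] = (main, single)
        else:
            cooccurrence.export_graph(net, outdir, f"network_{aspect}",
                                      layout_seed=layout_seed,
                                      image=write_figures)
            networks[aspect] = (net, None)

    dist = clustering.sample_distances(matrix, log2=True)
    tree = clustering.ward_dendrogram(dist)
    (outdir / "dendrogram.nwk").write_text(
        clustering.dendrogram_to_newick(tree) + "\n")
    tree.merge_table().to_csv(outdir / "merges.tsv", sep="\t", index=False)

    volcano = clustering.volcano_data(matrix)
    volcano.to_tsv(outdir / "volcano.tsv")
    phac = matrix.treatment_samples(["PhaC"])
    phabc = matrix.treatment_samples(["PhaBC"])
    scatter = clustering.scatter_data(matrix, phabc, phac)
    scatter.to_tsv(outdir / "scatter_phabc_phac.tsv")
    if write_figures:
        clustering.plot_dendrogram(tree, outdir / "dendrogram.png")
        clustering.plot_scatter(scatter, outdir / "scatter.png")
        clustering.plot_volcano(volcano, outdir / "volcano.png")

    return {"annotation": ann, "spots": spots, "meta": meta, "truth": truth,
            "matrix": matrix, "fold_change": fc, "scores": scores,
            "networks": networks, "distances": dist, "dendrogram": tree,
            "outdir": outdir}
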