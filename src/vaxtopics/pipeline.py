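"""End-to-end run: simulate -> dedup -> train -> cluster -> geometry -> report.

Ties the stages together the way the full analysis is meant to be run:
generate (or load) a corpus, de-duplicate it, train the stance classifier
and label every record, then per stance group select the number of topics
by silhouette, drop handle-only clusters, find the prominent topics,
compute radii and distinctiveness, compare the two stance groups by
t-test, and write every artifact (JSONL, CSV, JSON, SVG) under one output
directory.  Byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .clusters import (
    filter_prominent,
    is_handle_cluster,
    prominence_threshold,
    select_k,
    kmeans_fit,
    top_terms,
)
from .features import TweetVectorizer
from .geometry import compute_geometry, plot_geometry, prominent_vs_rest, two_sample_t
from .ingest import deduplicate, write_corpus
from .stance import StanceClassifier, save_model
from .synthetic import CorpusSpec, generate_corpus, write_synthetic_corpus

__all__ = ["run_pipeline", "analyze_stance_group"]

_WORD_KINDS = ("unigram", "hashtag", "mention")


def analyze_stance_group(
    X,
    vocab,
    k_range: Sequence[int],
    seed: int,
    prominence_fraction: float = 0.05,
    n_init: int = 10,
) -> dict:
    """Cluster one stance group and compute its topic geometry.

    Returns a dict with the selected k, silhouette curve, handle-excluded
    cluster ids, prominence threshold, the ProminentSet, the
    ClusterGeometry, and the prominent-vs-rest distinctiveness scores.
    """
    n = X.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("no feasible k in range for this group size")
    k_best, curve = select_k(X, ks, seed=seed, n_init=n_init)
    assign = kmeans_fit(X, k_best, seed=seed, n_init=n_init)

    excluded = []
    for cid in sorted(assign.sizes):
        top = top_terms(X, assign, cid, vocab, n=50, kinds=_WORD_KINDS)
        if top and is_handle_cluster(top, vocab):
            excluded.append(cid)

    n_net = n - sum(assign.sizes[c] for c in excluded)
    threshold = prominence_threshold(n_net, prominence_fraction)
    pset = filter_prominent(assign, threshold, excluded=excluded)
    geometry = compute_geometry(X, assign)
    scores = (
        prominent_vs_rest(geometry, pset.prominent, pset.rest)
        if pset.prominent and pset.rest
        else []
    )
    return {
        "n_tweets": n,
        "k": k_best,
        "curve": curve,
        "assignment": assign,
        "excluded": tuple(excluded),
        "threshold": threshold,
        "prominent_set": pset,
        "geometry": geometry,
        "scores": scores,
    }


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def run_pipeline(
    spec: CorpusSpec,
    outdir: str | Path,
    k_range: Sequence[int] = range(2, 9),
    C: float = 1.0,
    prominence_fraction: float = 0.05,
    n_init: int = 10,
    make_figures: bool = True,
) -> dict:
    """Run the whole analysis on a synthetic corpus; write all artifacts.

    The seed inside ``spec`` drives every random stage.  Returns the
    report dict (also written to ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = spec.seed

    # 1. simulate
    tweets, log = generate_corpus(spec, return_log=True)
    write_synthetic_corpus(tweets, outdir / "corpus.jsonl", log=log)

    # 2. dedup
    records = [t.to_record() for t in tweets]
    unique, n_dropped = deduplicate(records)
    write_corpus(unique, outdir / "dedup.jsonl")

    # 3. features + stance model (trained on the labeled records, then
    #    applied back to label the working set)
    texts = [r.text for r in unique]
    labels = np.asarray([r.label for r in unique])
    vec = TweetVectorizer().fit(texts)
    X = vec.transform(texts)
    clf = StanceClassifier(C=C, random_state=seed).fit(X, labels)
    save_model(clf, vec.vocabulary_, outdir / "model.json")
    predicted = clf.predict(X)

    # 4. per-stance clustering + geometry
    report: dict = {
        "seed": seed,
        "n_generated": len(tweets),
        "n_after_dedup": len(unique),
        "n_dropped": n_dropped,
        "class_counts": {c: int(np.sum(labels == c)) for c in clf.classes_},
        "predicted_counts": {c: int(np.sum(predicted == c)) for c in clf.classes_},
        "groups": {},
    }
    group_scores: dict[str, list[float]] = {}
    group_all_scores: dict[str, list[float]] = {}
    group_radii: dict[str, list[float]] = {}
    for stance in ("pro", "anti"):
        rows = np.flatnonzero(predicted == stance)
        if rows.size < 3:
            continue
        res = analyze_stance_group(
            X[rows],
            vec.vocabulary_,
            k_range,
            seed=seed,
            prominence_fraction=prominence_fraction,
            n_init=n_init,
        )
        assign = res["assignment"]
        geom = res["geometry"]
        pset = res["prominent_set"]

        _write_csv(
            outdir / f"clusters_{stance}.csv",
            ["tweet_id", "stance", "cluster_id"],
            [
                [unique[int(rows[i])].tweet_id, stance, int(assign.labels[i])]
                for i in range(rows.size)
            ],
        )
        _write_csv(
            outdir / f"silhouette_{stance}.csv",
            ["k", "silhouette"],
            [[k, s] for k, s in zip(res["curve"].k_values, res["curve"].scores)],
        )
        _write_csv(
            outdir / f"geometry_{stance}.csv",
            ["cluster_id", "radius", "size"],
            [[c, geom.radii[c], geom.sizes[c]] for c in geom.cluster_ids],
        )
        _write_csv(
            outdir / f"distances_{stance}.csv",
            ["from_id", "to_id", "score"],
            [[a, b, s] for (a, b), s in sorted(geom.scores.items())],
        )
        if make_figures and pset.prominent:
            plot_geometry(
                geom, pset.prominent, pset.rest, outdir / f"figure_{stance}.svg", seed=seed
            )

        kept = [c for c in geom.cluster_ids if c not in pset.excluded_handle_clusters]
        all_pair_scores = [
            s
            for (a, b), s in sorted(geom.scores.items())
            if a in kept and b in kept and math.isfinite(s)
        ]
        group_scores[stance] = res["scores"]
        group_all_scores[stance] = all_pair_scores
        group_radii[stance] = [geom.radii[c] for c in kept]
        report["groups"][stance] = {
            "n_tweets": res["n_tweets"],
            "k": res["k"],
            "excluded_handle_clusters": list(res["excluded"]),
            "prominence_threshold": res["threshold"],
            "prominent": list(pset.prominent),
            "rest": list(pset.rest),
            "mean_distinctiveness": float(np.mean(res["scores"])) if res["scores"] else None,
            "sd_distinctiveness": (
                float(np.std(res["scores"], ddof=1)) if len(res["scores"]) > 1 else None
            ),
            "mean_pairwise_distinctiveness": (
                float(np.mean(all_pair_scores)) if all_pair_scores else None
            ),
            "mean_radius": float(np.mean(group_radii[stance])),
        }

    # 5. group comparisons (anti vs pro, as distinctiveness and radii)
    if (
        len(group_scores.get("anti", [])) >= 2
        and len(group_scores.get("pro", [])) >= 2
    ):
        cmp_d = two_sample_t(group_scores["anti"], group_scores["pro"], tail="two")
        report["distinctiveness_comparison"] = asdict(cmp_d)
    if (
        len(group_all_scores.get("anti", [])) >= 2
        and len(group_all_scores.get("pro", [])) >= 2
    ):
        cmp_all = two_sample_t(group_all_scores["anti"], group_all_scores["pro"], tail="two")
        report["distinctiveness_comparison_all_pairs"] = asdict(cmp_all)
    if len(group_radii.get("anti", [])) >= 2 and len(group_radii.get("pro", [])) >= 2:
        cmp_r = two_sample_t(group_radii["anti"], group_radii["pro"], tail="two")
        report["radius_comparison"] = asdict(cmp_r)

    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, allow_nan=True)
    )
    return report
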