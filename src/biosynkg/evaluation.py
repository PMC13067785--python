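"""Ranking metrics, split protocols and experiment drivers.

Implements the full evaluation design: mean rank (MR), mean reciprocal
rank (MRR = (1/|Q|) Σ 1/r_q with r_q the rank of the first relevant
candidate), HITS@K for K ∈ {5, 10, 20}, Student-t confidence intervals
over independent runs, and three protocols — a temporal split (train on
reports before a cutoff year, test on later ones), an incremental year
series with a fixed test side, and leave-one-genus-out cross-validation
where all strains of a genus are held out together.  Evaluation is
*filtered* by default: a query's training positives are removed from its
candidate list so they cannot crowd out the test positives.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fusion_train import (
    FusedEmbeddingTable,
    RankingResult,
    TrainConfig,
    predict_ranking,
    train_model,
)
from .kg_core import KnowledgeGraph, TripleRecord, genus_of, temporal_subgraph

logger = logging.getLogger(__name__)

DEFAULT_HITS_KS = (5, 10, 20)

__all__ = [
    "RankingResult",
    "EvalReport",
    "mrr",
    "mean_rank",
    "hits_at_k",
    "confidence_interval",
    "normalize_rank_score",
    "temporal_protocol",
    "incremental_series",
    "leave_one_genus_out",
    "permutation_baseline",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _first_ranks(results: list[RankingResult]) -> list[int]:
    if not results:
        raise ValueError("no ranking results to score")
    ranks = []
    for r in results:
        rq = r.first_relevant_rank
        if rq is None:
            raise ValueError(f"query {r.query_id!r} has no relevant candidate")
        ranks.append(rq)
    return ranks


def mrr(results: list[RankingResult]) -> float:
    """Mean reciprocal rank of the first relevant candidate per query."""
    ranks = _first_ranks(results)
    return float(np.mean([1.0 / r for r in ranks]))


def mean_rank(results: list[RankingResult]) -> float:
    """Arithmetic mean of the first-relevant rank (the MR companion metric)."""
    return float(np.mean(_first_ranks(results)))


def hits_at_k(results: list[RankingResult], k: int) -> float:
    """Fraction of queries whose first relevant candidate ranks within top K."""
    if k < 1:
        raise ValueError("K must be >= 1")
    ranks = _first_ranks(results)
    return float(np.mean([r <= k for r in ranks]))


def compute_metrics(results: list[RankingResult], ks=DEFAULT_HITS_KS) -> dict[str, float]:
    out = {"MR": mean_rank(results), "MRR": mrr(results)}
    for k in ks:
        out[f"HITS@{k}"] = hits_at_k(results, k)
    return out


def confidence_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Student-t CI for the mean of a small number of independent runs."""
    values = np.asarray(list(values), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    m = float(values.mean())
    sd = float(values.std(ddof=1))
    half = stats.t.ppf(1.0 - (1.0 - level) / 2.0, len(values) - 1) * sd / np.sqrt(len(values))
    return (m - half, m + half)


def normalize_rank_score(result: RankingResult, convention: str = "reciprocal") -> dict[str, float]:
    """Per-candidate normalized scores in (0, 1]; rank 1 maps to 1.0.

    ``reciprocal`` (default): candidate at rank r scores 1/r.  ``minmax``:
    similarity scores rescaled so the best candidate scores 1 (degenerate
    all-equal lists score 1 everywhere).
    """
    if convention == "reciprocal":
        return {c: 1.0 / result.rank_of(c) for c in result.candidates}
    if convention == "minmax":
        arr = np.array(result.scores, dtype=float)
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            vals = np.ones_like(arr)
        else:
            vals = (arr - lo) / (hi - lo)
        return {c: float(v) for c, v in zip(result.candidates, vals)}
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-run metrics plus mean ± sd and 95% CI, for one protocol setting."""

    protocol: str
    per_run: list[dict[str, float]]
    level: float = 0.95
    extras: dict = field(default_factory=dict)

    @property
    def metrics(self) -> list[str]:
        return list(self.per_run[0])

    def mean(self, metric: str) -> float:
        return float(np.mean([r[metric] for r in self.per_run]))

    def sd(self, metric: str) -> float:
        vals = [r[metric] for r in self.per_run]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def ci(self, metric: str) -> tuple[float, float]:
        vals = [r[metric] for r in self.per_run]
        if len(vals) < 2:
            m = float(vals[0])
            return (m, m)
        return confidence_interval(vals, self.level)

    def validate(self) -> None:
        for run in self.per_run:
            if not 0.0 < run["MRR"] <= 1.0:
                raise ValueError(f"MRR out of (0,1]: {run['MRR']}")
            ks = sorted(int(m.split("@")[1]) for m in run if m.startswith("HITS@"))
            hits = [run[f"HITS@{k}"] for k in ks]
            if any(not 0.0 <= h <= 1.0 for h in hits):
                raise ValueError("HITS@K out of [0,1]")
            if any(hits[i] > hits[i + 1] + 1e-12 for i in range(len(hits) - 1)):
                raise ValueError("HITS@K must be nondecreasing in K")
            if run["MRR"] + 1e-12 < 1.0 / run["MR"]:
                raise ValueError("MRR >= 1/MR violated")

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(run=i, **r) for i, r in enumerate(self.per_run)]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m), "ci": list(self.ci(m))}
            for m in self.metrics
        }

    def to_json(self) -> str:
        return json.dumps(
            {"protocol": self.protocol, "per_run": self.per_run, "summary": self.summary()},
            indent=2,
        )

    def write(self, tsv_path, json_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                fh.write(self.to_json())


# ---------------------------------------------------------------------------
# protocol plumbing
# ---------------------------------------------------------------------------


def _positives_by_head(g: KnowledgeGraph) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for t in g.triples_with("synthesizes"):
        out.setdefault(t.head, set()).add(t.tail)
    return out


def rank_test_queries(
    table: FusedEmbeddingTable,
    test_positives: dict[str, set[str]],
    candidate_pool: list[str],
    train_positives: dict[str, set[str]] | None = None,
    filtered: bool = True,
) -> list[RankingResult]:
    """Rank the candidate pool for each test query.

    With ``filtered`` (default) each query's known training positives are
    removed from its candidate list, so a training fact never outranks the
    test positives it would trivially beat.
    """
    results = []
    for q in sorted(test_positives):
        known = (train_positives or {}).get(q, set())
        cands = [c for c in candidate_pool if not (filtered and c in known)]
        pos = test_positives[q] & set(cands)
        if not pos:
            logger.warning("query %s: no test positives left after filtering", q)
            continue
        if len(cands) < 2:
            continue
        results.append(predict_ranking(table, q, cands, positives=pos))
    if not results:
        raise ValueError("no evaluable test queries")
    return results


def permutation_baseline(
    results: list[RankingResult], rng: np.random.Generator, n_perm: int = 200
) -> dict[str, float]:
    """Metrics under random candidate orderings of the same queries.

    The chance floor the trained model is compared against: each query's
    candidate list is randomly permuted ``n_perm`` times and the metric
    means are reported.
    """
    mrrs, mrs = [], []
    hits = {k: [] for k in DEFAULT_HITS_KS}
    for _ in range(n_perm):
        ranks = []
        for r in results:
            perm = rng.permutation(len(r.candidates))
            first = min(
                int(np.where(perm == i)[0][0]) + 1
                for i, c in enumerate(r.candidates)
                if c in r.positives
            )
            ranks.append(first)
        mrrs.append(np.mean([1.0 / r for r in ranks]))
        mrs.append(np.mean(ranks))
        for k in hits:
            hits[k].append(np.mean([r <= k for r in ranks]))
    out = {"MR": float(np.mean(mrs)), "MRR": float(np.mean(mrrs))}
    for k in hits:
        out[f"HITS@{k}"] = float(np.mean(hits[k]))
    return out


def holdout_edge_recovery(
    g: KnowledgeGraph,
    model_cfg: TrainConfig,
    holdout_fraction: float = 0.3,
    seed: int = 0,
    n_perm: int = 200,
) -> dict[str, float]:
    """Planted-signal recovery: hold out synthesis edges, rank them back.

    A random ``holdout_fraction`` of the synthesizes edges is removed from
    training.  Each held-out edge becomes one query in the
    microbes-for-a-material direction — the direction with the large
    candidate space — under the standard filtered convention: every *other*
    known positive of that material (training or held-out) is removed from
    the candidate list, leaving a single relevant candidate per query.
    Returns the model MRR, the random-permutation baseline MRR on the same
    queries, and their ratio.
    """
    synth = g.triples_with("synthesizes")
    if len(synth) < 4:
        raise ValueError("too few synthesizes edges to hold out")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    idx = rng.permutation(len(synth))
    n_hold = max(1, int(round(holdout_fraction * len(synth))))
    held = [synth[i] for i in idx[:n_hold]]
    held_keys = {t.key() for t in held}
    train_g = KnowledgeGraph(classes=dict(g.classes), entities=dict(g.entities))
    train_g.add_triples([t for t in g.triples if t.key() not in held_keys], dedup=False)
    cfg = dataclasses.replace(model_cfg, seed=seed)
    _, table = train_model(train_g, cfg)
    known: dict[str, set[str]] = {}
    for t in synth:
        known.setdefault(t.tail, set()).add(t.head)
    strains = sorted(e.id for e in g.microbes())
    results = []
    for t in held:
        cands = [s for s in strains if s == t.head or s not in known[t.tail]]
        if len(cands) < 2:
            continue
        results.append(predict_ranking(table, t.tail, cands, positives={t.head}))
    model_mrr = mrr(results)
    base = permutation_baseline(results, np.random.default_rng(np.random.SeedSequence([seed, 42])),
                                n_perm=n_perm)
    return {
        "model_mrr": model_mrr,
        "baseline_mrr": base["MRR"],
        "ratio": model_mrr / base["MRR"],
        "n_heldout": float(len(results)),
    }


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def _run_split(
    train_g: KnowledgeGraph,
    test_positives: dict[str, set[str]],
    model_cfg: TrainConfig,
    runs: int,
    filtered: bool,
) -> list[dict[str, float]]:
    train_pos = _positives_by_head(train_g)
    materials = sorted(e.id for e in train_g.materials())
    per_run = []
    for run in range(runs):
        cfg = dataclasses.replace(model_cfg, seed=model_cfg.seed + run)
        _, table = train_model(train_g, cfg)
        results = rank_test_queries(table, test_positives, materials, train_pos, filtered)
        per_run.append(compute_metrics(results))
    return per_run


def temporal_protocol(
    g: KnowledgeGraph,
    model_cfg: TrainConfig,
    cutoff_year: int,
    runs: int = 3,
    filtered: bool = True,
) -> EvalReport:
    """Train on pre-cutoff synthesis reports, test on the cutoff-and-later ones.

    Each test microbe is ranked against the full material candidate set
    (minus its training positives when filtered); repeated over ``runs``
    seeds and aggregated with mean ± sd and a 95% CI.
    """
    train_g = temporal_subgraph(g, cutoff_year, "before")
    test_g = temporal_subgraph(g, cutoff_year, "from")
    test_pos = _positives_by_head(test_g)
    if not test_pos:
        raise ValueError(f"no test-side synthesizes triples at cutoff {cutoff_year}")
    per_run = _run_split(train_g, test_pos, model_cfg, runs, filtered)
    report = EvalReport(protocol=f"temporal-split cutoff={cutoff_year}", per_run=per_run)
    report.validate()
    return report


def incremental_series(
    g: KnowledgeGraph,
    model_cfg: TrainConfig,
    cutoffs: list[int],
    runs: int = 1,
    filtered: bool = True,
) -> tuple[list[EvalReport], pd.DataFrame]:
    """Growing training sets, fixed test side beyond the final cutoff.

    One report per cutoff; the trend table tracks how metrics move as the
    accumulated history grows.
    """
    if len(cutoffs) < 2:
        raise ValueError("need at least 2 cutoffs")
    cutoffs = sorted(cutoffs)
    final = cutoffs[-1]
    test_pos = _positives_by_head(temporal_subgraph(g, final, "from"))
    if not test_pos:
        raise ValueError(f"no test-side synthesizes triples beyond {final}")
    reports = []
    for cut in cutoffs:
        train_g = temporal_subgraph(g, cut, "before")
        overlap = [
            t for t in train_g.triples_with("synthesizes") if t.year is not None and t.year >= final
        ]
        if overlap:
            raise ValueError("training set overlaps the fixed test side")
        per_run = _run_split(train_g, test_pos, model_cfg, runs, filtered)
        rep = EvalReport(protocol=f"incremental cutoff={cut} (test>= {final})", per_run=per_run)
        rep.validate()
        reports.append(rep)
    trend = pd.DataFrame(
        [
            {"cutoff": cut, **{m: rep.mean(m) for m in rep.metrics}}
            for cut, rep in zip(cutoffs, reports)
        ]
    )
    return reports, trend


def leave_one_genus_out(
    g: KnowledgeGraph,
    model_cfg: TrainConfig,
    runs: int = 1,
    filtered: bool = True,
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """Hold out each genus's synthesis edges in turn; test on them.

    Folds partition the positive edge set; a genus without edges is skipped
    with a warning.  Returns per-genus reports plus a fold manifest.
    """
    synth = g.triples_with("synthesizes")
    by_genus: dict[str, list[TripleRecord]] = {}
    for t in synth:
        genus = genus_of(g, t.head)
        by_genus.setdefault(str(genus), []).append(t)
    genera_with_edges = sorted(k for k, v in by_genus.items() if v)
    all_genera = {str(genus_of(g, e.id)) for e in g.microbes()}
    for gen in sorted(all_genera - set(genera_with_edges)):
        logger.warning("genus %s has no synthesizes edges; fold skipped", gen)
    if len(genera_with_edges) < 2:
        raise ValueError("leave-one-genus-out needs >= 2 genera with synthesizes edges")
    reports: dict[str, EvalReport] = {}
    manifest_rows = []
    for genus in genera_with_edges:
        held = by_genus[genus]
        held_keys = {t.key() for t in held}
        train_g = KnowledgeGraph(classes=dict(g.classes), entities=dict(g.entities))
        train_g.add_triples([t for t in g.triples if t.key() not in held_keys], dedup=False)
        test_pos: dict[str, set[str]] = {}
        for t in held:
            test_pos.setdefault(t.head, set()).add(t.tail)
        per_run = _run_split(train_g, test_pos, model_cfg, runs, filtered)
        rep = EvalReport(protocol=f"leave-one-genus-out genus={genus}", per_run=per_run)
        rep.validate()
        reports[genus] = rep
        manifest_rows.append(
            {"genus": genus, "n_test_edges": len(held), "n_test_microbes": len(test_pos)}
        )
    manifest = pd.DataFrame(manifest_rows)
    return reports, manifest
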