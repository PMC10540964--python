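"""End-to-end retrieval pipeline: phantom generation, preprocessing, weak
pair mining, training of both similarity calculators, index construction,
and evaluated retrieval.

The stages mirror the three-phase framework: an offline data-generation
and training phase, an offline preprocessing/indexing phase, and an
online retrieval phase. With a ``workdir`` the pipeline is resumable —
each stage writes its artifact next to a sidecar carrying a hash of the
configuration that produced it, and is skipped when both still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as case_io
from .index import APConfig, RetrievalSphere, build_index, retrieve_pruned, \
    retrieve_sequential, top_k
from .metrics import RankedJudgment, mean_ap, phantom_relevance, precision, summarize
from .pairs import make_contour_pairs, make_detail_pairs, pairs_to_arrays, \
    save_pairs, load_pairs
from .phantom import CaseSeries, PhantomConfig, generate_dataset
from .preprocess import mask_case
from .simnet import NetConfig, ScoreFusionConfig, batched_logits, \
    build_cs_calculator, build_ds_calculator, load_checkpoint, save_checkpoint, \
    sigmoid, train_calculator

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Every knob of the end-to-end pipeline, with desk-scale defaults."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    net: NetConfig = field(default_factory=NetConfig)
    ap: APConfig = field(default_factory=APConfig)
    fusion: ScoreFusionConfig = field(default_factory=ScoreFusionConfig)
    threshold_hu: float = -320.0
    n_contour_pairs: int = 120
    n_detail_pairs: int = 120
    warp_magnitude: float = 0.05
    negative_gap: float = 0.3
    cs_threshold: float = 0.8
    ratio_sim_to_dissim: int = 3
    queries_per_case: int = 2
    k: int = 5
    relevance_gap: int = 2
    seed: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        self.net.validate()
        self.ap.validate()
        self.fusion.validate()

    @staticmethod
    def from_json(path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        phantom_raw = {k: tuple(v) if k == "stripe_count_range" else v
                       for k, v in raw.get("phantom", {}).items()}
        return RunConfig(
            phantom=PhantomConfig(**phantom_raw),
            net=NetConfig(**{k: tuple(v) if k == "widths" else v
                             for k, v in raw.get("net", {}).items()}),
            ap=APConfig(**raw.get("ap", {})),
            fusion=ScoreFusionConfig(**raw.get("fusion", {})),
            **{k: v for k, v in raw.items()
               if k not in ("phantom", "net", "ap", "fusion")})


def _cfg_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


class _Cache:
    """Skip-if-unchanged stage cache keyed by a config hash chain."""

    def __init__(self, workdir: Optional[Path]) -> None:
        self.workdir = Path(workdir) if workdir else None
        if self.workdir:
            self.workdir.mkdir(parents=True, exist_ok=True)

    def get(self, name: str, cfg_hash: str):
        if not self.workdir:
            return None
        sidecar = self.workdir / f"{name}.hash.json"
        if sidecar.exists() and json.loads(sidecar.read_text())["hash"] == cfg_hash:
            return self.workdir / name
        return None

    def mark(self, name: str, cfg_hash: str, seed: int) -> None:
        if self.workdir:
            (self.workdir / f"{name}.hash.json").write_text(
                json.dumps({"hash": cfg_hash, "seed": seed}))


def pairwise_distance_matrix(slices_raw: Sequence[np.ndarray],
                             slices_masked: Sequence[np.ndarray],
                             cs_model, ds_model, alpha: float,
                             batch_size: int = 64) -> np.ndarray:
    """Symmetric matrix of 1 - SScore over a slice list.

    Contour scores are computed on the raw slices, detail scores on the
    parenchyma-masked renditions; pairs are evaluated in one order and
    mirrored.
    """
    n = len(slices_raw)
    ii, jj = np.triu_indices(n, k=1)
    d = np.zeros((n, n))
    if len(ii) == 0:
        return d
    raw = np.stack([np.stack([slices_raw[i], slices_raw[j]]) for i, j in zip(ii, jj)])
    sc = sigmoid(batched_logits(cs_model, raw, batch_size))
    del raw
    msk = np.stack([np.stack([slices_masked[i], slices_masked[j]])
                    for i, j in zip(ii, jj)])
    sd = sigmoid(batched_logits(ds_model, msk, batch_size))
    score = alpha * sc + (1 - alpha) * sd
    d[ii, jj] = d[jj, ii] = 1.0 - score
    return d


def query_distances(query_raw, query_masked, slices_raw, slices_masked,
                    cs_model, ds_model, alpha: float,
                    batch_size: int = 64) -> np.ndarray:
    """1 - SScore from one query to every database slice."""
    raw = np.stack([np.stack([query_raw, s]) for s in slices_raw])
    sc = sigmoid(batched_logits(cs_model, raw, batch_size))
    msk = np.stack([np.stack([query_masked, s]) for s in slices_masked])
    sd = sigmoid(batched_logits(ds_model, msk, batch_size))
    return 1.0 - (alpha * sc + (1 - alpha) * sd)


def run_pipeline(config: RunConfig, workdir=None) -> Dict:
    """Execute every stage and return the collated report."""
    config.validate()
    cache = _Cache(workdir)
    t0 = time.time()
    report: Dict = {"config_hash": _cfg_hash(asdict(config)), "seed": config.seed,
                    "stages": {}}

    def stage(name):
        logger.info("stage %-14s (t=%.1fs)", name, time.time() - t0)

    # ---- 1. phantom dataset -------------------------------------------
    stage("phantom")
    h_phantom = _cfg_hash(asdict(config.phantom))
    cases = generate_dataset(config.phantom)
    if cache.workdir:
        case_io.write_dataset_manifest(cache.workdir / "dataset_manifest.json",
                                       cases, config.phantom.seed)
        cache.mark("dataset_manifest.json", h_phantom, config.phantom.seed)
    report["stages"]["phantom"] = {"n_cases": len(cases),
                                   "n_slices": cases[0].n_slices,
                                   "hash": h_phantom}

    # ---- 2. preprocessing ---------------------------------------------
    stage("preprocess")
    masked_cases = [CaseSeries(c.case_id, mask_case(c.slices, config.threshold_hu),
                               c.spacing) for c in cases]
    report["stages"]["preprocess"] = {"threshold_hu": config.threshold_hu}

    # ---- 3. contour pairs + CS training -------------------------------
    stage("train-cs")
    h_cs = _cfg_hash([h_phantom, asdict(config.net), config.n_contour_pairs,
                      config.warp_magnitude, config.negative_gap, config.seed])
    cs_path = cache.get("cs_model.npz", h_cs)
    if cs_path:
        cs_model = load_checkpoint(cs_path)
        cs_history: List[float] = []
        logger.info("reusing cached CS model")
    else:
        contour_pairs = make_contour_pairs(
            cases, config.n_contour_pairs, config.warp_magnitude,
            config.negative_gap, seed=config.seed)
        cs_model = build_cs_calculator(config.net)
        cs_model, cs_history = train_calculator(cs_model, contour_pairs, config.net)
        if cache.workdir:
            save_checkpoint(cache.workdir / "cs_model.npz", cs_model, "cs")
            cache.mark("cs_model.npz", h_cs, config.seed)
    report["stages"]["train_cs"] = {"loss_history": cs_history, "hash": h_cs}

    # ---- 4. detail pairs + DS training --------------------------------
    stage("train-ds")

    def cs_scorer(a, b):
        return float(sigmoid(cs_model.forward(np.stack([a, b])[None])[0]))

    h_ds = _cfg_hash([h_cs, config.n_detail_pairs, config.cs_threshold,
                      config.ratio_sim_to_dissim, config.seed])
    ds_path = cache.get("ds_model.npz", h_ds)
    if ds_path:
        ds_model = load_checkpoint(ds_path)
        ds_history = []
        logger.info("reusing cached DS model")
    else:
        detail_pairs = make_detail_pairs(
            masked_cases, cs_scorer, config.n_detail_pairs,
            cs_threshold=config.cs_threshold,
            ratio_sim_to_dissim=config.ratio_sim_to_dissim,
            seed=config.seed + 1, scoring_cases=cases,
            max_candidate_draws=300)
        ds_model = build_ds_calculator(config.net)
        ds_model, ds_history = train_calculator(ds_model, detail_pairs, config.net)
        if cache.workdir:
            save_checkpoint(cache.workdir / "ds_model.npz", ds_model, "ds")
            cache.mark("ds_model.npz", h_ds, config.seed)
    report["stages"]["train_ds"] = {"loss_history": ds_history, "hash": h_ds}

    # ---- 5. database / query split ------------------------------------
    stage("split")
    rng = np.random.default_rng(config.seed + 2)
    db_raw, db_masked, db_prov = [], [], []
    queries = []
    for ci, (case, mcase) in enumerate(zip(cases, masked_cases)):
        qs = set(rng.choice(np.arange(1, case.n_slices - 1),
                            size=min(config.queries_per_case, case.n_slices - 2),
                            replace=False).tolist())
        for r in range(case.n_slices):
            if r in qs:
                queries.append((case.case_id, r, case.slices[r], mcase.slices[r]))
            else:
                db_raw.append(case.slices[r])
                db_masked.append(mcase.slices[r])
                db_prov.append((case.case_id, r))

    # ---- 6. learned distances + index ---------------------------------
    stage("index")
    alpha = config.fusion.alpha
    dmat = pairwise_distance_matrix(db_raw, db_masked, cs_model, ds_model, alpha)
    idx = build_index(len(db_raw), None, config.ap, distance_matrix=dmat)
    report["stages"]["index"] = {
        "n_database": len(db_raw), "n_clusters": len(idx.clusters),
        "radii": [round(c.radius, 4) for c in idx.clusters]}

    # ---- 7. retrieval + evaluation ------------------------------------
    stage("retrieve")
    judgments, per_query_precision = [], []
    pruned_evals, seq_evals, recalls = [], [], []
    for qcase, qlayer, qraw, qmasked in queries:
        dq = query_distances(qraw, qmasked, db_raw, db_masked,
                             cs_model, ds_model, alpha)
        ranked = top_k(config.k, len(db_raw), lambda i: dq[i])
        rel = [phantom_relevance(qcase, qlayer, *db_prov[i], config.relevance_gap)
               for i, _ in ranked]
        j = RankedJudgment(f"{qcase}:{qlayer}", [i for i, _ in ranked], rel)
        judgments.append(j)
        per_query_precision.append(precision(j))

        # range query at the k-th neighbour's distance: pruned vs sequential
        r_r = ranked[-1][1]
        sphere = RetrievalSphere(query=(qcase, qlayer), r_R=r_r)
        res_p, n_evals = retrieve_pruned(sphere, idx, lambda i: dq[i])
        res_s = retrieve_sequential(sphere, len(db_raw), lambda i: dq[i])
        pruned_evals.append(n_evals)
        seq_evals.append(len(db_raw))
        recalls.append(1.0 if len(res_s) == 0
                       else len(np.intersect1d(res_p, res_s)) / len(res_s))

    mx, mn, avg = summarize(per_query_precision)
    report["database_provenance"] = [[c, int(r)] for c, r in db_prov]
    report["rankings"] = [{"query_case": j.query_id.split(":")[0],
                           "query_layer": int(j.query_id.split(":")[1]),
                           "ranked_ids": [int(i) for i in j.ranked_ids]}
                          for j in judgments]
    report["retrieval"] = {
        "n_queries": len(queries), "k": config.k,
        "precision_max": mx, "precision_min": mn, "precision_avg": avg,
        "mAP": mean_ap(judgments),
        "pruned_evaluations_mean": float(np.mean(pruned_evals)),
        "sequential_evaluations_mean": float(np.mean(seq_evals)),
        "pruning_speedup": float(np.mean(seq_evals) / np.mean(pruned_evals)),
        "pruned_recall_vs_sequential": float(np.mean(recalls)),
    }
    report["runtime_s"] = round(time.time() - t0, 2)
    if cache.workdir:
        (cache.workdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
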