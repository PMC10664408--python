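"""Shared fixtures.

The expensive end-to-end scenario runs (source pretraining + transfer on
800-cell pairs, three seeds each) are session-scoped so the scenario suite
computes each condition once.
"""
from __future__ import annotations

import numpy as np
import pytest

from gdec import (
    ExpressionMatrix,
    GdecConfig,
    GeneGraph,
    SimulationConfig,
    TransferConfig,
    hungarian_accuracy,
    ari,
    pretrain_source,
    simulate_gene_graph,
    simulate_pair,
    transfer_and_finetune,
)
from gdec.simulate import sample_prior_labels

SEEDS = (1, 2, 3)


@pytest.fixture
def path_graph() -> GeneGraph:
    return GeneGraph(["A", "B", "C"], {("A", "B"), ("B", "C")})


def random_graph(n_nodes: int, p: float, seed: int) -> GeneGraph:
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_nodes)]
    iu, ju = np.triu_indices(n_nodes, k=1)
    pick = rng.random(len(iu)) < p
    edges = {(genes[i], genes[j]) for i, j in zip(iu[pick], ju[pick])}
    return GeneGraph(genes, edges)


def _scenario(seed: int, missing=()):
    cfg = SimulationConfig(missing_types_in_source=missing, seed=seed)
    (src, src_lab), (tgt, tgt_lab) = simulate_pair(cfg)
    graph = simulate_gene_graph(cfg)
    prior = sample_prior_labels(tgt_lab, 0.1, seed=seed + 100)
    return cfg, src, src_lab, tgt, tgt_lab, graph, prior


@pytest.fixture(scope="session")
def cross_batch_runs():
    """Per-seed accuracies: full pipeline, scratch-on-10%, no-GCN, no-transfer."""
    out = []
    for seed in SEEDS:
        _, src, src_lab, tgt, tgt_lab, graph, prior = _scenario(seed)
        bundle = pretrain_source(src, src_lab, graph, GdecConfig.compact().with_seed(seed))
        _, res = transfer_and_finetune(bundle, tgt, prior, TransferConfig(seed=seed))
        full = hungarian_accuracy(tgt_lab, res)
        full_ari = ari(tgt_lab, res)

        idx = {c: i for i, c in enumerate(tgt.cell_ids)}
        rows = [idx[c] for c in prior.cell_ids]
        sub = ExpressionMatrix(
            tgt.values[rows], [tgt.cell_ids[i] for i in rows], list(tgt.gene_ids)
        )
        b2 = pretrain_source(sub, prior, graph, GdecConfig.compact().with_seed(seed + 500))
        _, res2 = transfer_and_finetune(b2, tgt, None, TransferConfig(finetune_iters=0, seed=seed))
        scratch = hungarian_accuracy(tgt_lab, res2)

        b3 = pretrain_source(src, src_lab, graph,
                             GdecConfig.compact(use_gcn=False).with_seed(seed))
        _, res3 = transfer_and_finetune(b3, tgt, prior, TransferConfig(seed=seed))
        no_gcn = hungarian_accuracy(tgt_lab, res3)

        b4 = pretrain_source(tgt, tgt_lab, graph, GdecConfig.compact().with_seed(seed + 900))
        no_transfer = hungarian_accuracy(tgt_lab, b4.source_result)

        out.append(
            {"full": full, "full_ari": full_ari, "scratch": scratch,
             "no_gcn": no_gcn, "no_transfer": no_transfer}
        )
    return out


@pytest.fixture(scope="session")
def rejection_runs():
    """Unknown-rate statistics with type 3 held out of the source."""
    out = []
    for seed in SEEDS:
        _, src, src_lab, tgt, tgt_lab, graph, prior = _scenario(seed, missing=(3,))
        bundle = pretrain_source(src, src_lab, graph, GdecConfig.compact().with_seed(seed))
        tcfg = TransferConfig.open_set(seed=seed)
        _, res = transfer_and_finetune(bundle, tgt, prior, tcfg)
        held = np.array([l == "type3" for l in tgt_lab.labels])
        unk = np.array([m == "unknown" for m in res.mapped_type])
        out.append(
            {
                "held_unknown_rate": float(unk[held].mean()),
                "seen_unknown_rate": float(unk[~held].mean()),
                "accuracy": hungarian_accuracy(tgt_lab, res),
                "result": res,
                "truth": tgt_lab,
            }
        )
    return out
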