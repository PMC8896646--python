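"""End-to-end study pipelines at configurable scale.

One call runs the whole chain for a simulated spike-in study: generate
control and case OTU tables, fit the compositional Bayesian correlation
model per group, draw balanced labeled posterior networks, train the
graph classifier over repeated stratified splits, and (optionally) run
the knock-out importance search per run.

The reduced default scale (p = 20 taxa before filtering, 100 networks per
class, 3 classifier runs of 30 epochs, 2 chains of 300 warmup + 300 kept
draws) keeps a full study in the minutes range on one CPU while
preserving the qualitative behavior of the full-scale protocol (800
networks per class, 10 runs, 80-100 epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import dgcnn, graph_dataset, importance, inference, simulator


@dataclass
class StudyConfig:
    """Scale knobs for a simulated spike-in study."""

    case_number: int = 1
    n_samples: int = 100
    n_taxa: int = 20
    beta: float = 1.0
    chains: int = 2
    warmup: int = 300
    iters: int = 300
    networks_per_class: int = 100
    n_runs: int = 3
    epochs: int = 30
    train_fraction: float = 0.8
    importance_subsample: int = 20
    dgcnn: dgcnn.DgcnnConfig = field(default_factory=dgcnn.DgcnnConfig)


@dataclass
class StudyResult:
    """Everything a simulated study produces."""

    study: simulator.SimulatedStudy
    posterior_control: inference.BanoccPosterior
    posterior_case: inference.BanoccPosterior
    dataset: graph_dataset.GraphDataset
    runs: list[dict]                     # per-run: model, history, final val metrics
    importance_runs: list[importance.ImportanceResult]

    def mean_val_metric(self, name: str) -> float:
        return float(np.mean([r["val"][name] for r in self.runs]))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_study(
    config: StudyConfig,
    seed: int = 0,
    run_importance: bool = True,
    shuffle_labels: bool = False,
) -> StudyResult:
    """Run the full simulate -> infer -> classify (-> explain) pipeline.

    ``shuffle_labels`` randomly permutes the network labels before the
    train/validation splits (a null-model control: validation accuracy
    should then hover around chance).
    """
    (seed_sim, seed_fit0, seed_fit1, seed_draw0, seed_draw1,
     seed_assemble, seed_runs, seed_shuffle) = _spawn_seeds(seed, 8)

    params = simulator.default_marginals(config.n_taxa)
    study = simulator.build_case(
        config.case_number, params=params, n_samples=config.n_samples,
        beta=config.beta, seed=seed_sim,
    )

    post_ctrl = inference.sample_posterior(
        study.control, chains=config.chains, warmup=config.warmup,
        iters=config.iters, seed=seed_fit0,
    )
    post_case = inference.sample_posterior(
        study.case, chains=config.chains, warmup=config.warmup,
        iters=config.iters, seed=seed_fit1,
    )

    nets0 = inference.draw_networks(post_ctrl, config.networks_per_class, label=0, seed=seed_draw0)
    nets1 = inference.draw_networks(post_case, config.networks_per_class, label=1, seed=seed_draw1)
    dataset = graph_dataset.assemble_dataset(nets0, nets1, seed=seed_assemble)

    if shuffle_labels:
        rng = np.random.default_rng(seed_shuffle)
        labels = rng.permutation(dataset.labels)
        networks = [replace(net, label=int(lbl))
                    for net, lbl in zip(dataset.networks, labels)]
        dataset = graph_dataset.GraphDataset(networks=networks, node_info=dataset.node_info)

    run_seeds = _spawn_seeds(seed_runs, config.n_runs)
    runs: list[dict] = []
    imp_runs: list[importance.ImportanceResult] = []
    for r, rseed in enumerate(run_seeds):
        train_set, val_set = graph_dataset.train_val_split(
            dataset, config.train_fraction, seed=rseed
        )
        cfg = replace(config.dgcnn, epochs=config.epochs, seed=rseed)
        model, history = dgcnn.train(train_set, val_set, cfg)
        val_metrics = dgcnn.evaluate(model, val_set)
        runs.append({"run": r, "model": model, "history": history, "val": val_metrics})
        if run_importance:
            case_nets = [net for net in val_set.networks if net.label == 1]
            imp_runs.append(
                importance.run_importance(
                    model, case_nets, n=min(5, len(dataset.taxon_ids)),
                    subsample=config.importance_subsample, seed=rseed,
                )
            )
    return StudyResult(
        study=study,
        posterior_control=post_ctrl,
        posterior_case=post_case,
        dataset=dataset,
        runs=runs,
        importance_runs=imp_runs,
    )
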