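"""Model/Results interface tying encoder, simulator and trainer together.

``SpikingClassifier`` is constructed from a feature matrix and labels (or a
DataFrame); it freezes the encoder on the training data's per-feature
ranges, builds the class codebook and the network topology, and ``fit()``
runs the evolutionary trainer, returning a ``SpikingClassifierResults``
that carries the fitted synapse matrices, the training trace, diagnostics
and prediction/scoring methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation
from .data import TabularDataset
from .encoding import ClassCodebook, EncoderConfig, encode_dataset, infer_feature_ranges, make_codebook
from .evolution import GAConfig, Genome, TrainingTrace, evolve, genome_to_synapses, network_output_times
from .lif import LIFConfig, NetworkShape

__all__ = ["SpikingClassifier", "SpikingClassifierResults", "repeat_fit"]


class SpikingClassifier:
    """Single-spike feed-forward spiking network classifier.

    Parameters
    ----------
    features, labels
        Training data: (n, F) numeric matrix and n class labels.
    n_hidden
        Hidden-layer width (default 12).
    fields_per_feature, beta
        Population-encoder settings (L Gaussian fields per feature, spread
        adjustment beta).
    lif, ga
        ``LIFConfig`` and ``GAConfig``; defaults follow the standard
        hyper-parameters (tau_m=10 ms, tau_s=5 ms, gain 100, threshold
        1 mV, T=20 ms; population 100, 20% elitism, crossover 0.8,
        mutation 0.1).
    codebook_start, codebook_spacing
        First class target time (ms) and gap between consecutive class
        targets; defaults 11 and 1 put k classes at 11, 12, ... ms.
    feature_ranges
        Optional explicit per-feature (min, max); inferred from the
        training features when omitted.
    """

    def __init__(
        self,
        features,
        labels,
        *,
        n_hidden: int = 12,
        fields_per_feature: int = 4,
        beta: float = 1.5,
        lif: LIFConfig | None = None,
        ga: GAConfig | None = None,
        codebook_start: float = 11.0,
        codebook_spacing: float = 1.0,
        feature_ranges=None,
    ):
        self.features = np.asarray(features, dtype=float)
        self.labels = list(labels)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.labels):
            raise ValueError("features must be (n, F) with one label per row")
        self.lif = lif or LIFConfig()
        self.ga = ga or GAConfig()
        if feature_ranges is None:
            feature_ranges = infer_feature_ranges(self.features)
        self.encoder = EncoderConfig(
            n_fields=fields_per_feature,
            beta=beta,
            dt=self.lif.dt,
            feature_ranges=tuple(feature_ranges),
        )
        self.classes_ = sorted(set(self.labels))
        self.codebook: ClassCodebook = make_codebook(
            self.classes_,
            start_time=codebook_start,
            spacing=codebook_spacing,
            t_max_encoding=self.encoder.t_max,
            t_total=self.lif.t_total,
        )
        self.shape = NetworkShape(self.encoder.n_input_neurons, n_hidden, 1)
        self.spike_matrix = encode_dataset(self.features, self.encoder)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str, **kwargs) -> "SpikingClassifier":
        features = df.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(features, df[label_column].tolist(), **kwargs)

    @classmethod
    def from_dataset(cls, dataset: TabularDataset, **kwargs) -> "SpikingClassifier":
        return cls(dataset.features, dataset.labels, **kwargs)

    def encode(self, features) -> np.ndarray:
        """Encode new instances with the training-frozen encoder."""
        return encode_dataset(features, self.encoder)

    def fit(self, seed: int | None = 0) -> "SpikingClassifierResults":
        """Run the evolutionary trainer and return the fitted results."""
        trace = evolve(
            self.spike_matrix,
            self.labels,
            self.codebook,
            self.shape,
            self.lif,
            self.ga,
            seed=seed,
        )
        return SpikingClassifierResults(model=self, trace=trace, genome=trace.best_genome)


@dataclass
class SpikingClassifierResults:
    """Fitted parameters, training diagnostics and prediction methods."""

    model: SpikingClassifier
    trace: TrainingTrace
    genome: Genome

    @property
    def params(self):
        """(input->hidden, hidden->output) synapse sets of the best genome."""
        return genome_to_synapses(self.genome, self.model.shape)

    @property
    def convergence_generation(self) -> int:
        return self.trace.convergence_generation

    @property
    def train_accuracy(self) -> float:
        return self.trace.final_train_accuracy

    @property
    def ce(self) -> float:
        """Computational efficiency dt/(T*G) of this run."""
        return evaluation.compute_ce(self.model.lif.dt, self.model.lif.t_total, self.convergence_generation)

    def predict_times(self, features) -> np.ndarray:
        """Output-neuron first-spike time per instance (NaN where silent)."""
        spikes = self.model.encode(features)
        return network_output_times(self.genome, spikes, self.model.shape, self.model.lif)

    def predict(self, features) -> list:
        return evaluation.decode_outputs(
            self.predict_times(features), self.model.codebook, self.model.lif.t_total
        )

    def score(self, features, labels) -> float:
        """Accuracy (%) on a labelled dataset."""
        return evaluation.accuracy(self.predict(features), list(labels))

    def confusion(self, features, labels) -> np.ndarray:
        return evaluation.confusion_matrix(list(labels), self.predict(features), self.model.classes_)

    def report(self, features, labels, **meta) -> evaluation.EvalReport:
        pred = self.predict(features)
        return evaluation.EvalReport(
            accuracy=evaluation.accuracy(pred, list(labels)),
            confusion=evaluation.confusion_matrix(list(labels), pred, self.model.classes_),
            labels=self.model.classes_,
            ce=self.ce,
            meta=meta,
        )

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels style."""
        m = self.model
        rows = [
            ("topology (M-N-P)", f"{m.shape.n_input}-{m.shape.n_hidden}-{m.shape.n_output}"),
            ("genes (weights + delays)", f"{self.genome.n_genes}"),
            ("classes / codebook (ms)", ", ".join(f"{c}:{t:g}" for c, t in m.codebook.times.items())),
            ("encoder fields per feature", f"{m.encoder.n_fields} (beta={m.encoder.beta:g})"),
            ("dt / T (ms)", f"{m.lif.dt:g} / {m.lif.t_total:g}"),
            ("population / elites", f"{m.ga.pop_size} / {m.ga.n_elite}"),
            ("generations run", f"{self.trace.n_generations}"),
            ("convergence generation G", f"{self.convergence_generation}"),
            ("best fitness 1/(1+MSE)", f"{self.trace.best_fitness[-1]:.4f}"),
            ("training accuracy", f"{self.train_accuracy:.2f}%"),
            ("computational efficiency CE", f"{self.ce:.3e}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Spiking network classifier — evolutionary fit", "=" * 46]
        lines += [f"{k.ljust(width)} : {v}" for k, v in rows]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write trace, synapse matrices and run metadata as CSV/YAML text."""
        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trace.to_dataframe().to_csv(out / "trace.csv", index=False)
        ih, ho = self.params
        pd.DataFrame(ih.weights).to_csv(out / "weights_input_hidden.csv", index=False)
        pd.DataFrame(ih.delays.astype(int)).to_csv(out / "delays_input_hidden.csv", index=False)
        pd.DataFrame(ho.weights).to_csv(out / "weights_hidden_output.csv", index=False)
        pd.DataFrame(ho.delays.astype(int)).to_csv(out / "delays_hidden_output.csv", index=False)
        meta = {
            "seed": self.trace.seed,
            "topology": [self.model.shape.n_input, self.model.shape.n_hidden, self.model.shape.n_output],
            "fields_per_feature": self.model.encoder.n_fields,
            "beta": self.model.encoder.beta,
            "feature_ranges": [list(r) for r in self.model.encoder.feature_ranges],
            "codebook": {str(k): float(v) for k, v in self.model.codebook.times.items()},
            "lif": {
                "tau_m": self.model.lif.tau_m,
                "tau_s": self.model.lif.tau_s,
                "r_m": self.model.lif.r_m,
                "theta": self.model.lif.theta,
                "v_rest": self.model.lif.v_rest,
                "dt": self.model.lif.dt,
                "t_total": self.model.lif.t_total,
            },
            "ga": {
                "pop_size": self.model.ga.pop_size,
                "elite_frac": self.model.ga.elite_frac,
                "crossover_rate": self.model.ga.crossover_rate,
                "mutation_rate": self.model.ga.mutation_rate,
                "max_generations": self.model.ga.max_generations,
            },
            "convergence_generation": self.convergence_generation,
            "train_accuracy": self.train_accuracy,
            "ce": self.ce,
        }
        (out / "run.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def repeat_fit(
    train: TabularDataset,
    test: TabularDataset,
    n_repeats: int = 10,
    seed: int = 0,
    **model_kwargs,
):
    """Repeat the stochastic fit with distinct seeds.

    Returns (results_list, summary DataFrame with one row per repeat plus
    mean and sample-sd rows over training/test accuracy and CE).
    """
    rows, results = [], []
    for r in range(n_repeats):
        model = SpikingClassifier.from_dataset(train, **model_kwargs)
        res = model.fit(seed=seed + r)
        results.append(res)
        rows.append(
            {
                "seed": seed + r,
                "train_accuracy": res.train_accuracy,
                "test_accuracy": res.score(test.features, test.labels),
                "convergence_generation": res.convergence_generation,
                "ce": res.ce,
            }
        )
    table = pd.DataFrame(rows)
    stats = table[["train_accuracy", "test_accuracy", "ce"]].agg(["mean", "std"])
    return results, table, stats
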