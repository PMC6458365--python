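"""Cell-type classification from single-cell viscosity.

A deliberately small pattern-recognition setup: each cell contributes one
scalar (its cytoplasmic viscosity, log10-transformed by default), and a
two-layer feed-forward network — one hidden layer of sigmoid units, a
two-unit softmax output — is trained with cross-entropy loss and
validation-based early stopping on a stratified 70/15/15
train/validation/test split.  The headline figure is the *successful
classification rate*: accuracy over all three splits combined (50% means
the two populations are indistinguishable, 100% perfectly separable).

``bayes_rate_oracle`` integrates the two class densities numerically and
returns the best accuracy any classifier could reach on the generating
log-normals; the trained network should approach it from below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .synthetic import PopulationSpec


@dataclass(frozen=True)
class ClassifierConfig:
    """Training configuration (defaults mirror common pattern-recognition practice)."""

    hidden_units: int = 10
    max_epochs: int = 400
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    input_transform: str = "log10"  # or "identity"
    learning_rate: float = 0.05
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError(f"hidden_units must be >= 1, got {self.hidden_units}")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.input_transform not in ("log10", "identity"):
            raise ValueError(f"unknown input_transform {self.input_transform!r}")


@dataclass
class ClassifierReport:
    """Confusion matrix and rates, combined over train+validation+test."""

    confusion: np.ndarray          # 2x2 counts, rows=true, cols=predicted
    overall_rate: float            # combined accuracy (the headline)
    split_rates: dict              # accuracy per split
    split_sizes: dict
    per_class_correct: tuple[int, int]
    per_class_total: tuple[int, int]
    labels: tuple[str, str]
    seed: int

    def summary(self) -> str:
        a, b = self.labels
        cm = self.confusion
        lines = [
            f"Successful classification rate (combined): {self.overall_rate * 100:.1f}%",
            f"  split accuracies: " + ", ".join(
                f"{k} {v * 100:.1f}% (n={self.split_sizes[k]})"
                for k, v in self.split_rates.items()
            ),
            "  confusion matrix (rows = true, cols = predicted):",
            f"    {'':>10} {a:>10} {b:>10}",
            f"    {a:>10} {cm[0, 0]:>10d} {cm[0, 1]:>10d}",
            f"    {b:>10} {cm[1, 0]:>10d} {cm[1, 1]:>10d}",
            f"  seed: {self.seed}",
        ]
        return "\n".join(lines)


class PatternNet:
    """1 -> hidden sigmoid -> 2 softmax network on standardized inputs."""

    def __init__(self, cfg: ClassifierConfig, labels: tuple[str, str] = ("A", "B")):
        self.cfg = cfg
        self.labels = labels
        self.W1: np.ndarray | None = None  # (1, h)
        self.b1 = self.W2 = self.b2 = None
        self.x_mean = 0.0
        self.x_sd = 1.0

    # -- plumbing ---------------------------------------------------------
    def _transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cfg.input_transform == "log10":
            bad = np.nonzero(values <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"log10 transform requires positive viscosities; cell index "
                    f"{int(bad[0])} has value {values[bad[0]]!r}"
                )
            values = np.log10(values)
        return values

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = 1.0 / (1.0 + np.exp(-(x[:, None] @ self.W1 + self.b1)))
        z = h @ self.W2 + self.b2
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return h, ez / ez.sum(axis=1, keepdims=True)

    def predict_proba(self, values) -> np.ndarray:
        if self.W1 is None:
            raise ValueError("model has not been trained")
        x = (self._transform(values) - self.x_mean) / self.x_sd
        return self._forward(x)[1]

    def predict(self, values) -> np.ndarray:
        """Class labels; exact posterior ties resolve to the first label."""
        proba = self.predict_proba(values)
        return np.asarray(self.labels)[
            np.where(proba[:, 1] > proba[:, 0], 1, 0)
        ]

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "labels": list(self.labels),
            "input_transform": self.cfg.input_transform,
            "hidden_units": self.cfg.hidden_units,
            "x_mean": self.x_mean,
            "x_sd": self.x_sd,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatternNet":
        data = json.loads(Path(path).read_text())
        cfg = ClassifierConfig(
            hidden_units=data["hidden_units"], input_transform=data["input_transform"]
        )
        net = cls(cfg, tuple(data["labels"]))
        net.W1 = np.array(data["W1"])
        net.b1 = np.array(data["b1"])
        net.W2 = np.array(data["W2"])
        net.b2 = np.array(data["b2"])
        net.x_mean = data["x_mean"]
        net.x_sd = data["x_sd"]
        return net


def _stratified_split(
    n: int, cfg: ClassifierConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permute 0..n-1 and cut into train/val/test index arrays."""
    perm = rng.permutation(n)
    n_tr = int(round(cfg.train_frac * n))
    n_val = int(round(cfg.val_frac * n))
    n_tr = min(n_tr, n - 2)  # keep at least one sample outside training
    return perm[:n_tr], perm[n_tr:n_tr + n_val], perm[n_tr + n_val:]


def _cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))


def train(
    values_a,
    values_b,
    cfg: ClassifierConfig | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[PatternNet, ClassifierReport]:
    """Train the two-layer network on two single-cell viscosity collections.

    The split is stratified per class; early stopping monitors the
    validation cross-entropy and restores the best weights ("halted when no
    further improvement can be made").  Fully deterministic under
    ``cfg.seed``.
    """
    cfg = cfg or ClassifierConfig()
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    for name, v in ((labels[0], values_a), (labels[1], values_b)):
        if v.size < 3:
            raise ValueError(f"class {name!r} has {v.size} cells; need >= 3")
    if values_a.size + values_b.size < 20:
        raise ValueError("need at least 20 cells in total")

    net = PatternNet(cfg, labels)
    x_raw = np.concatenate([net._transform(values_a), net._transform(values_b)])
    y = np.concatenate(
        [np.zeros(values_a.size, dtype=int), np.ones(values_b.size, dtype=int)]
    )

    rng = np.random.default_rng(cfg.seed)
    tr_a, va_a, te_a = _stratified_split(values_a.size, cfg, rng)
    tr_b, va_b, te_b = _stratified_split(values_b.size, cfg, rng)
    off = values_a.size
    idx_tr = np.concatenate([tr_a, tr_b + off])
    idx_va = np.concatenate([va_a, va_b + off])
    idx_te = np.concatenate([te_a, te_b + off])

    net.x_mean = float(np.mean(x_raw[idx_tr]))
    net.x_sd = float(np.std(x_raw[idx_tr])) or 1.0
    x = (x_raw - net.x_mean) / net.x_sd

    h = cfg.hidden_units
    net.W1 = rng.normal(0.0, 1.0, (1, h))
    net.b1 = np.zeros(h)
    net.W2 = rng.normal(0.0, 1.0 / np.sqrt(h), (h, 2))
    net.b2 = np.zeros(2)

    # Adam, full batch
    params = [net.W1, net.b1, net.W2, net.b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    x_tr, y_tr = x[idx_tr], y[idx_tr]
    x_va, y_va = x[idx_va], y[idx_va]
    onehot = np.eye(2)[y_tr]
    best = (np.inf, None)
    wait = 0
    for epoch in range(1, cfg.max_epochs + 1):
        hid, proba = net._forward(x_tr)
        dz = (proba - onehot) / len(y_tr)          # (n, 2)
        gW2 = hid.T @ dz
        gb2 = dz.sum(axis=0)
        dh = (dz @ net.W2.T) * hid * (1.0 - hid)   # (n, h)
        gW1 = x_tr[:, None].T @ dh
        gb1 = dh.sum(axis=0)
        for i, (p, g) in enumerate(zip(params, [gW1, gb1, gW2, gb2])):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mh = m[i] / (1 - beta1**epoch)
            vh = v[i] / (1 - beta2**epoch)
            p -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)

        if x_va.size:
            val_loss = _cross_entropy(net._forward(x_va)[1], y_va)
        else:
            val_loss = _cross_entropy(net._forward(x_tr)[1], y_tr)
        if val_loss < best[0] - 1e-7:
            best = (val_loss, [p.copy() for p in params])
            wait = 0
        else:
            wait += 1
            if wait > cfg.patience:
                break
    if best[1] is not None:
        net.W1, net.b1, net.W2, net.b2 = best[1]

    # report over the combined dataset, plus per-split rates
    pred = np.argmax(net._forward(x)[1], axis=1)
    confusion = np.zeros((2, 2), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    split_rates, split_sizes = {}, {}
    for name, idx in (("train", idx_tr), ("validation", idx_va), ("test", idx_te)):
        split_sizes[name] = int(idx.size)
        split_rates[name] = float(np.mean(pred[idx] == y[idx])) if idx.size else float("nan")
    report = ClassifierReport(
        confusion=confusion,
        overall_rate=float(np.trace(confusion) / confusion.sum()),
        split_rates=split_rates,
        split_sizes=split_sizes,
        per_class_correct=(int(confusion[0, 0]), int(confusion[1, 1])),
        per_class_total=(int(confusion[0].sum()), int(confusion[1].sum())),
        labels=labels,
        seed=cfg.seed,
    )
    return net, report


def classify_new(model: PatternNet, values) -> tuple[np.ndarray, np.ndarray]:
    """Labels and posterior scores for new cells from a fitted model."""
    proba = model.predict_proba(values)
    return model.predict(values), proba


def bayes_rate_oracle(
    spec_a: PopulationSpec,
    spec_b: PopulationSpec,
    priors: tuple[float, float] | None = None,
    n_grid: int = 200_001,
) -> float:
    """Best achievable accuracy for two known log-normal populations.

    Integrates the class-weighted log-scale densities and returns the
    accuracy of the pointwise maximum-posterior rule.  Point-mass
    populations (``log_sigma = 0``) are handled analytically.
    """
    if priors is None:
        total = spec_a.n_cells + spec_b.n_cells
        priors = (spec_a.n_cells / total, spec_b.n_cells / total)
    wa, wb = priors
    if abs(wa + wb - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")

    if spec_a.log_sigma == 0 and spec_b.log_sigma == 0:
        if spec_a.log_median == spec_b.log_median:
            return max(wa, wb)
        return 1.0
    if spec_a.log_sigma == 0 or spec_b.log_sigma == 0:
        # a point mass is almost surely separable from a continuous density
        return 1.0

    sa, sb = spec_a.log_sigma, spec_b.log_sigma
    lo = min(spec_a.log_median - 8 * sa, spec_b.log_median - 8 * sb)
    hi = max(spec_a.log_median + 8 * sa, spec_b.log_median + 8 * sb)
    x = np.linspace(lo, hi, n_grid)
    pa = wa * norm.pdf(x, spec_a.log_median, sa)
    pb = wb * norm.pdf(x, spec_b.log_median, sb)
    return float(np.trapezoid(np.maximum(pa, pb), x))


class CellTypeClassifier:
    """Model-object facade: hold two populations, ``fit()`` to a report.

    Example
    -------
    >>> clf = CellTypeClassifier(va, vb, labels=("H1299", "A549"))
    >>> res = clf.fit(seed=7)
    >>> print(res.report.summary())
    """

    def __init__(
        self,
        values_a,
        values_b,
        labels: tuple[str, str] = ("A", "B"),
        config: ClassifierConfig | None = None,
    ):
        self.values_a = np.asarray(values_a, dtype=float)
        self.values_b = np.asarray(values_b, dtype=float)
        self.labels = labels
        self.config = config or ClassifierConfig()

    def fit(self, seed: int | None = None) -> "ClassifierResults":
        cfg = self.config
        if seed is not None:
            from dataclasses import replace

            cfg = replace(cfg, seed=seed)
        model, report = train(self.values_a, self.values_b, cfg, self.labels)
        return ClassifierResults(model=model, report=report, config=cfg)


@dataclass
class ClassifierResults:
    model: PatternNet
    report: ClassifierReport
    config: ClassifierConfig
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        return self.report.summary()

    def predict(self, values):
        return self.model.predict(values)
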