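"""Co-distillation and knowledge distillation of pluggable student scorers.

Co-distillation is mutual learning against a fixed aggregate: all students
score every protein, the grids are combined (elementwise minimum = maximum
confidence, or mean), the aggregate is precomputed and *held fixed*, and each
student is then trained independently with an MSE loss against its own
mean-shifted copy of the aggregate. Rounds can be chained with different
aggregators (for example a min round followed by avg rounds), each round
continuing from the previous round's student states. Knowledge distillation
is the degenerate case with a single frozen teacher.

Students here are deliberately small: a table student with free per-entry
parameters (one grid per known protein) and a context student that is linear
in a one-hot local sequence window and therefore generalizes to unseen
proteins. Both honor the same contract — ``score(protein) -> LLRMatrix`` and
``fit_step(proteins, targets) -> loss`` — so a heavyweight scorer can be
dropped in. The wild-type-zero property is preserved by construction, and
masked/wild-type entries are excluded from every loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from scipy.optimize import minimize

from .aggregate import (
    ScoreStack,
    aggregate_mean,
    aggregate_min,
    matrix_mean,
    mean_shift_targets,
)
from .alphabet import N_AA
from .scoring import LLRMatrix, ProteinRecord

__all__ = [
    "StudentModel",
    "TableStudent",
    "ContextStudent",
    "TrainConfig",
    "RoundSchedule",
    "DistillTargets",
    "build_targets",
    "train_student",
    "codistill_round",
    "run_schedule",
    "knowledge_distill",
]


class StudentModel(Protocol):
    """Trainable scorer contract used throughout this module."""

    name: str

    def score(self, protein: ProteinRecord) -> LLRMatrix: ...

    def fit_step(
        self,
        proteins: Sequence[ProteinRecord],
        targets: Mapping[str, LLRMatrix],
    ) -> float:  # returns the scalar MSE after masking
        ...


def _loss_entries(
    student_scores: LLRMatrix, target: LLRMatrix
) -> tuple[np.ndarray, np.ndarray]:
    sel = student_scores.variant_mask() & target.variant_mask()
    return student_scores.scores[sel], target.scores[sel]


def _mse(students: "StudentModel", proteins, targets) -> float:
    num, den = 0.0, 0
    for p in proteins:
        a, b = _loss_entries(students.score(p), targets[p.id])
        num += float(np.sum((a - b) ** 2))
        den += a.size
    return num / max(den, 1)


class TableStudent:
    """Full-capacity student: free LLR parameters per known protein entry.

    Each gradient step on the per-entry squared error contracts the residual
    by (1 - 2 lr); the default lr = 0.5 is the exact minimizing step for this
    quadratic, so a step lands on the target. Plain gradient descent,
    deterministic. Scores only proteins seen at construction.
    """

    def __init__(
        self,
        proteins: Sequence[ProteinRecord],
        init: Mapping[str, LLRMatrix] | None = None,
        lr: float = 0.5,
        name: str = "table",
    ):
        self.name = name
        self.lr = lr
        self._wt = {p.id: p.wt_indices for p in proteins}
        self._mask = {}
        self.params: dict[str, np.ndarray] = {}
        for p in proteins:
            if init is not None and p.id in init:
                self.params[p.id] = init[p.id].scores.copy()
                self._mask[p.id] = init[p.id].mask.copy()
            else:
                self.params[p.id] = np.zeros((len(p), N_AA))
                m = np.ones((len(p), N_AA), dtype=bool)
                m[self._wt[p.id] < 0] = False
                self._mask[p.id] = m

    def score(self, protein: ProteinRecord) -> LLRMatrix:
        if protein.id not in self.params:
            raise KeyError(f"table student has no parameters for {protein.id}")
        return LLRMatrix(
            protein.id,
            self.params[protein.id].copy(),
            self._wt[protein.id].copy(),
            self._mask[protein.id].copy(),
        )

    def fit_step(self, proteins, targets) -> float:
        for p in proteins:
            t = targets[p.id]
            sel = self._mask[p.id] & t.variant_mask()
            grid = self.params[p.id]
            grid[sel] -= 2.0 * self.lr * (grid[sel] - t.scores[sel])
        return _mse(self, proteins, targets)

    def clone(self) -> "TableStudent":
        return copy.deepcopy(self)


class ContextStudent:
    """Low-capacity student, linear in a one-hot local sequence window.

    Features at position t are the one-hot encoding of the 2k+1 residues
    around t plus a bias; a weight matrix maps features to 20 logits and the
    LLR is logit(alt) - logit(wt), so wild-type entries are zero by
    construction. Fitting runs L-BFGS on the masked MSE with an analytic
    gradient; the window radius is the capacity knob.
    """

    def __init__(
        self,
        window_radius: int = 2,
        l2: float = 1e-6,
        init_scale: float = 0.0,
        seed: int = 0,
        maxiter_per_step: int = 40,
        name: str = "context",
    ):
        self.name = name
        self.k = window_radius
        self.l2 = l2
        self.maxiter = maxiter_per_step
        self.n_features = (2 * self.k + 1) * N_AA + 1
        rng = np.random.default_rng(seed)
        self.W = (
            rng.normal(0.0, init_scale, size=(self.n_features, N_AA))
            if init_scale > 0
            else np.zeros((self.n_features, N_AA))
        )

    def _features(self, protein: ProteinRecord) -> np.ndarray:
        idx = protein.wt_indices
        L = idx.size
        X = np.zeros((L, self.n_features))
        X[:, -1] = 1.0
        for off in range(-self.k, self.k + 1):
            src = np.arange(L) + off
            ok = (src >= 0) & (src < L)
            aa = idx[src[ok]]
            valid = aa >= 0
            rows = np.flatnonzero(ok)[valid]
            X[rows, (off + self.k) * N_AA + aa[valid]] = 1.0
        return X

    def _predict(self, X: np.ndarray, wt: np.ndarray, W: np.ndarray) -> np.ndarray:
        logits = X @ W
        ref = logits[np.arange(len(wt)), np.maximum(wt, 0)]
        pred = logits - ref[:, None]
        pred[wt < 0] = 0.0
        return pred

    def score(self, protein: ProteinRecord) -> LLRMatrix:
        X = self._features(protein)
        wt = protein.wt_indices
        pred = self._predict(X, wt, self.W)
        mask = np.ones((len(protein), N_AA), dtype=bool)
        mask[wt < 0] = False
        return LLRMatrix(protein.id, pred, wt, mask)

    def fit_step(self, proteins, targets) -> float:
        data = []
        n_entries = 0
        for p in proteins:
            X = self._features(p)
            wt = p.wt_indices
            t = targets[p.id]
            sel = t.variant_mask()
            sel[wt < 0] = False
            data.append((X, wt, t.scores, sel))
            n_entries += int(sel.sum())
        n_entries = max(n_entries, 1)

        def objective(w_flat: np.ndarray):
            W = w_flat.reshape(self.n_features, N_AA)
            total = 0.0
            G = np.zeros_like(W)
            for X, wt, tscores, sel in data:
                pred = self._predict(X, wt, W)
                R = np.where(sel, pred - tscores, 0.0)
                total += float(np.sum(R**2))
                M = R.copy()
                rows = wt >= 0
                M[rows, wt[rows]] -= R[rows].sum(axis=1)
                G += X.T @ M
            loss = total / n_entries + self.l2 * float(np.sum(W**2))
            grad = 2.0 * G / n_entries + 2.0 * self.l2 * W
            return loss, grad.ravel()

        res = minimize(
            objective,
            self.W.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.maxiter},
        )
        self.W = res.x.reshape(self.n_features, N_AA)
        return _mse(self, proteins, targets)

    def clone(self) -> "ContextStudent":
        return copy.deepcopy(self)


@dataclass
class TrainConfig:
    """Per-round training settings (defaults mirror a short 5-epoch schedule)."""

    epochs: int = 5
    seed: int = 0
    validation_fraction: float = 0.0
    validation_ids: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation fraction must be in [0, 1)")


@dataclass
class RoundSchedule:
    """Ordered aggregator tags per round, e.g. ('min', 'avg', 'avg')."""

    aggregators: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.aggregators) < 1:
            raise ValueError("schedule needs at least one round")
        for a in self.aggregators:
            if a not in ("min", "avg", "mean"):
                raise ValueError(f"unknown aggregator {a!r}")

    def __iter__(self):
        return iter(self.aggregators)


@dataclass
class DistillTargets:
    """Fixed, mean-shifted target grids: per student, per protein."""

    per_student: dict[str, dict[str, LLRMatrix]]
    shifts: dict[str, float]
    aggregator: str
    round_index: int = 0


def build_targets(
    stacks: Mapping[str, ScoreStack],
    aggregator: str,
    base_means: Mapping[str, float],
    round_index: int = 0,
) -> DistillTargets:
    """Aggregate the stacks and mean-shift the result once per student.

    The shift aligns the pooled target mean (over all proteins' non-wild-type
    entries) with each student's own base score mean, and is then held
    constant: targets are never recomputed during training.
    """
    if aggregator == "min":
        agg_fn = aggregate_min
    elif aggregator in ("avg", "mean"):
        agg_fn = aggregate_mean
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    aggregates = {pid: agg_fn(stack).matrix for pid, stack in stacks.items()}
    pooled = np.concatenate(
        [m.scores[m.variant_mask()] for m in aggregates.values()]
    )
    agg_mean = float(pooled.mean())
    per_student: dict[str, dict[str, LLRMatrix]] = {}
    shifts: dict[str, float] = {}
    for sname, bmean in base_means.items():
        shift = bmean - agg_mean
        shifts[sname] = shift
        grids = {}
        for pid, m in aggregates.items():
            g = m.copy()
            sel = g.variant_mask()
            g.scores[sel] += shift
            grids[pid] = g
        per_student[sname] = grids
    return DistillTargets(per_student, shifts, aggregator, round_index)


def train_student(
    student: StudentModel,
    proteins: Sequence[ProteinRecord],
    targets: Mapping[str, LLRMatrix],
    config: TrainConfig,
) -> list[float]:
    """Train one student against fixed targets; returns the per-epoch loss trace.

    The final training MSE must not exceed the initial MSE; a non-finite loss
    aborts with the offending epoch index.
    """
    missing = [p.id for p in proteins if p.id not in targets]
    if missing:
        raise ValueError(f"targets missing for proteins {missing}")
    trace = []
    for epoch in range(config.epochs):
        loss = student.fit_step(proteins, targets)
        if not np.isfinite(loss):
            raise ArithmeticError(f"training diverged at epoch {epoch}: loss={loss}")
        trace.append(float(loss))
    return trace


def _pooled_base_mean(student: StudentModel, proteins) -> float:
    vals = []
    for p in proteins:
        m = student.score(p)
        vals.append(m.scores[m.variant_mask()])
    return float(np.concatenate(vals).mean())


def codistill_round(
    students: Sequence[StudentModel],
    proteins: Sequence[ProteinRecord],
    aggregator: str = "min",
    config: TrainConfig | None = None,
    eval_fn: Callable[[Sequence[StudentModel]], dict] | None = None,
    round_index: int = 0,
    online: bool = False,
) -> dict:
    """One co-distillation round: score, aggregate, fix targets, train each student.

    The default precomputes the aggregate once and trains every student
    against that fixed target. ``online=True`` instead re-aggregates the
    students' current scores before every epoch (true mutual learning); the
    per-student mean shifts stay anchored to the round-start score means.
    Returns a report with per-student loss traces, shift constants and, when
    ``eval_fn`` is given, pre-/post-round benchmark metrics.
    """
    if len(students) == 0:
        raise ValueError("need at least one student")
    config = config or TrainConfig()
    report: dict = {"aggregator": aggregator, "round": round_index, "online": online}
    if eval_fn is not None:
        report["pre"] = eval_fn(students)

    def current_targets() -> DistillTargets:
        stacks = {
            p.id: ScoreStack(
                p.id, [s.name for s in students], [s.score(p) for s in students]
            )
            for p in proteins
        }
        return build_targets(stacks, aggregator, base_means, round_index)

    base_means = {s.name: _pooled_base_mean(s, proteins) for s in students}
    if online:
        traces: dict[str, list[float]] = {s.name: [] for s in students}
        epoch_cfg = TrainConfig(epochs=1, seed=config.seed)
        for _ in range(config.epochs):
            targets = current_targets()
            for s in students:
                traces[s.name] += train_student(
                    s, proteins, targets.per_student[s.name], epoch_cfg
                )
        report["shifts"] = targets.shifts
        report["loss_traces"] = traces
    else:
        targets = current_targets()
        report["shifts"] = targets.shifts
        report["loss_traces"] = {}
        for s in students:
            trace = train_student(s, proteins, targets.per_student[s.name], config)
            report["loss_traces"][s.name] = trace
    if eval_fn is not None:
        report["post"] = eval_fn(students)
    return report


def run_schedule(
    students: Sequence[StudentModel],
    proteins: Sequence[ProteinRecord],
    schedule: RoundSchedule,
    config: TrainConfig | None = None,
    eval_fn: Callable[[Sequence[StudentModel]], dict] | None = None,
) -> list[dict]:
    """Run a multi-round schedule, each round continuing from the previous state."""
    history = []
    for r, agg in enumerate(schedule):
        history.append(
            codistill_round(
                students, proteins, agg, config, eval_fn=eval_fn, round_index=r
            )
        )
    return history


CHECKPOINT_VERSION = 1


def save_student(student: "TableStudent | ContextStudent", path) -> None:
    """Serialize a toy student to JSON with a format version field."""
    import json

    if isinstance(student, TableStudent):
        payload = {
            "kind": "table",
            "lr": student.lr,
            "params": {pid: g.tolist() for pid, g in student.params.items()},
            "wt": {pid: w.tolist() for pid, w in student._wt.items()},
            "mask": {pid: m.tolist() for pid, m in student._mask.items()},
        }
    elif isinstance(student, ContextStudent):
        payload = {
            "kind": "context",
            "window_radius": student.k,
            "l2": student.l2,
            "maxiter": student.maxiter,
            "W": student.W.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize student of type {type(student)!r}")
    payload["format_version"] = CHECKPOINT_VERSION
    payload["name"] = student.name
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_student(path) -> "TableStudent | ContextStudent":
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload.get('format_version')}")
    if payload["kind"] == "table":
        s = TableStudent([], lr=payload["lr"], name=payload["name"])
        s.params = {pid: np.asarray(g) for pid, g in payload["params"].items()}
        s._wt = {pid: np.asarray(w, dtype=np.int64) for pid, w in payload["wt"].items()}
        s._mask = {pid: np.asarray(m, dtype=bool) for pid, m in payload["mask"].items()}
        return s
    s = ContextStudent(
        window_radius=payload["window_radius"],
        l2=payload["l2"],
        maxiter_per_step=payload["maxiter"],
        name=payload["name"],
    )
    s.W = np.asarray(payload["W"])
    return s


def load_run_config(path) -> tuple[TrainConfig, RoundSchedule]:
    """Read a YAML or JSON config mirroring TrainConfig and RoundSchedule.

    Expected keys: ``train`` (epochs, seed, validation_fraction) and
    ``schedule`` (list of aggregator tags).
    """
    import json

    import yaml

    text = open(path).read()
    cfg = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    train = TrainConfig(**cfg.get("train", {}))
    schedule = RoundSchedule(tuple(cfg.get("schedule", ["min"])))
    return train, schedule


def knowledge_distill(
    teacher: StudentModel,
    student: StudentModel,
    proteins: Sequence[ProteinRecord],
    config: TrainConfig | None = None,
) -> list[float]:
    """Train ``student`` to reproduce ``teacher``'s LLR grids (teacher frozen)."""
    config = config or TrainConfig()
    targets = {p.id: teacher.score(p) for p in proteins}
    return train_student(student, proteins, targets, config)
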