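"""Help-requirement classifiers: stacked sparse autoencoders + softmax.

Four architectures share the same two-stage training recipe:

* ``single_modal_skeleton`` — three hidden layers of 80 on the 200-d
  motion features;
* ``single_modal_eeg`` — three hidden layers of 80 on the 80-d mental
  features;
* ``early_fusion`` — the two feature vectors are concatenated (280-d)
  before the first of three hidden layers of 80 ("skeleton-EEG");
* ``late_fusion`` — each modality is pretrained through its own
  two-layer branch of 80 units, the two 80-d codes are concatenated and
  a joint third hidden layer of width 160 feeds the head ("integrated").

Stage 1 pretrains every branch (and the joint layer) greedily and
unsupervised; stage 2 trains a softmax regression head on the top code
and then refines the whole network — all encoder weights plus the head —
by backpropagation on the labeled data.  Decoder weights are frozen
after pretraining; they play no role at prediction time.

The module is organised statsmodels-style: :class:`HelpRequestSAE` is
the model object built from data, ``fit()`` returns a
:class:`SAEResults` carrying the trained network, its training
diagnostics, ``predict``/``predict_proba`` and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sae
from .exceptions import ConfigurationError, InputError, NotFittedError, TrainingError
from .sae import AutoencoderLayer, SparsityConfig, TrainConfig

ARCHITECTURES = (
    "single_modal_skeleton",
    "single_modal_eeg",
    "early_fusion",
    "late_fusion",
)

#: L2 penalty on the head weights; the softmax is otherwise
#: non-identifiable (and unbounded under separable data).
HEAD_L2 = 1e-4


# --------------------------------------------------------------------------
# softmax regression head


@dataclass
class SoftmaxHead:
    """Multinomial logistic head: one weight vector plus bias per class."""

    W: np.ndarray  # (k, d)
    b: np.ndarray  # (k,)

    @property
    def n_classes(self) -> int:
        return self.W.shape[0]


def softmax_probabilities(head: SoftmaxHead, z: np.ndarray) -> np.ndarray:
    """Class probabilities exp(θ_j·z) / Σ_i exp(θ_i·z), overflow-safe."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    if Z.shape[1] != head.W.shape[1]:
        raise InputError("feature dimension does not match the head")
    scores = Z @ head.W.T + head.b
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs[0] if single else probs


def softmax_cost(
    head: SoftmaxHead, Z: np.ndarray, labels: np.ndarray, l2: float = HEAD_L2
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy J(θ) over the batch, and its exact gradients.

    ``labels`` are class indices in 0..k−1.  J includes an L2 term
    ``l2/2 · ||W||²``; at θ = 0 it equals ln k exactly.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels)
    if Z.shape[0] != labels.shape[0] or Z.shape[0] < 1:
        raise InputError("Z and labels must align and be nonempty")
    k = head.n_classes
    if labels.min() < 0 or labels.max() >= k:
        raise InputError("label outside 0..k-1")
    q = Z.shape[0]
    probs = softmax_probabilities(head, Z)
    nll = -np.log(np.clip(probs[np.arange(q), labels], 1e-300, None)).mean()
    J = nll + 0.5 * l2 * float(np.sum(head.W**2))

    onehot = np.zeros_like(probs)
    onehot[np.arange(q), labels] = 1.0
    delta = (probs - onehot) / q  # (q, k)
    grads = {"W": delta.T @ Z + l2 * head.W, "b": delta.sum(axis=0)}
    return float(J), grads


def train_softmax_head(
    Z: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    cfg: TrainConfig | None = None,
    l2: float = HEAD_L2,
) -> tuple[SoftmaxHead, list[float]]:
    """Deterministic gradient-based minimization of J(θ) from a zero start.

    Full-batch L-BFGS: deterministic for fixed inputs, and the final
    cost never exceeds the initial ln k.
    """
    from scipy.optimize import minimize

    cfg = cfg or TrainConfig(learning_rate=1.0, max_iters=300)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    k, d = n_classes, Z.shape[1]

    def fun(theta):
        head = SoftmaxHead(theta[: k * d].reshape(k, d), theta[k * d :])
        J, g = softmax_cost(head, Z, labels, l2)
        return J, np.concatenate([g["W"].ravel(), g["b"]])

    trace = [fun(np.zeros(k * d + k))[0]]
    if cfg.max_iters == 0:
        return SoftmaxHead(np.zeros((k, d)), np.zeros(k)), trace + [trace[0]]
    res = minimize(
        fun,
        np.zeros(k * d + k),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_iters},
    )
    if np.isnan(res.fun):
        raise TrainingError("head cost diverged to NaN")
    x = res.x if res.fun <= trace[0] else np.zeros(k * d + k)
    head = SoftmaxHead(x[: k * d].reshape(k, d), x[k * d :])
    trace.append(min(res.fun, trace[0]))
    return head, trace


# --------------------------------------------------------------------------
# architectures


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan for one of the four architectures.

    ``branch_sizes`` holds the hidden sizes of each per-modality branch
    (one branch for the single-modal and early-fusion kinds) and
    ``joint_sizes`` any layers after the branches merge.
    """

    kind: str
    motion_dim: int = 200
    mental_dim: int = 80
    branch_sizes: tuple[tuple[int, ...], ...] = ()
    joint_sizes: tuple[int, ...] = ()

    @staticmethod
    def default(kind: str, motion_dim: int = 200, mental_dim: int = 80, hidden: int = 80):
        if kind in ("single_modal_skeleton", "single_modal_eeg", "early_fusion"):
            return ArchitectureSpec(
                kind, motion_dim, mental_dim, ((hidden, hidden, hidden),), ()
            )
        if kind == "late_fusion":
            return ArchitectureSpec(
                kind,
                motion_dim,
                mental_dim,
                ((hidden, hidden), (hidden, hidden)),
                (2 * hidden,),
            )
        raise ConfigurationError(f"unknown architecture kind: {kind!r}")

    def input_slices(self) -> list[slice]:
        """Slices of the model's input matrix feeding each branch."""
        if self.kind == "single_modal_skeleton":
            return [slice(0, self.motion_dim)]
        if self.kind == "single_modal_eeg":
            return [slice(0, self.mental_dim)]
        if self.kind == "early_fusion":
            return [slice(0, self.motion_dim + self.mental_dim)]
        if self.kind == "late_fusion":
            return [
                slice(0, self.motion_dim),
                slice(self.motion_dim, self.motion_dim + self.mental_dim),
            ]
        raise ConfigurationError(f"unknown architecture kind: {self.kind!r}")

    def validate(self) -> None:
        if self.kind not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture kind: {self.kind!r}")
        if len(self.branch_sizes) != len(self.input_slices()):
            raise ConfigurationError("branch count does not match the architecture")
        if self.kind == "late_fusion" and not self.joint_sizes:
            raise ConfigurationError("late fusion needs a joint layer")
        if any(s < 1 for branch in self.branch_sizes for s in branch) or any(
            s < 1 for s in self.joint_sizes
        ):
            raise ConfigurationError("layer sizes must be positive")


@dataclass
class _Network:
    """A trained (or pretrained) stack: branches, joint layers, head."""

    spec: ArchitectureSpec
    branches: list[list[AutoencoderLayer]] = field(default_factory=list)
    joint: list[AutoencoderLayer] = field(default_factory=list)
    head: SoftmaxHead | None = None

    def top_code(self, X: np.ndarray) -> np.ndarray:
        codes = [
            sae.encode_stack(X[:, sl], stack)
            for sl, stack in zip(self.spec.input_slices(), self.branches)
        ]
        H = np.concatenate(codes, axis=1)
        return sae.encode_stack(H, self.joint)

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        if self.head is None:
            raise NotFittedError("network head is not trained")
        return softmax_probabilities(self.head, self.top_code(np.atleast_2d(X)))


def build_model(spec: ArchitectureSpec, n_classes: int = 9, seed: int = 0) -> _Network:
    """Untrained network with seeded layers matching the spec's plan.

    The head starts at zero weights (uniform probabilities); training
    replaces it.
    """
    spec.validate()
    net = _Network(spec)
    s = seed
    for sl, sizes in zip(spec.input_slices(), spec.branch_sizes):
        stack, n_in = [], sl.stop - sl.start
        for h in sizes:
            stack.append(sae.init_layer(n_in, h, s))
            n_in, s = h, s + 1
        net.branches.append(stack)
    n_in = sum(b[-1].n_hidden for b in net.branches)
    for h in spec.joint_sizes:
        net.joint.append(sae.init_layer(n_in, h, s))
        n_in, s = h, s + 1
    net.head = SoftmaxHead(np.zeros((n_classes, n_in)), np.zeros(n_classes))
    return net


# --------------------------------------------------------------------------
# refine stage: backpropagation through all encoders + head


def _refine_cost_grads(net: _Network, X: np.ndarray, labels: np.ndarray):
    """Cross-entropy (+ head L2) and gradients for every encoder and the head."""
    spec = net.spec
    acts_branches = []
    codes = []
    for sl, stack in zip(spec.input_slices(), net.branches):
        acts = [X[:, sl]]
        for layer in stack:
            acts.append(layer.encode(acts[-1]))
        acts_branches.append(acts)
        codes.append(acts[-1])
    H = np.concatenate(codes, axis=1)
    acts_joint = [H]
    for layer in net.joint:
        acts_joint.append(layer.encode(acts_joint[-1]))
    top = acts_joint[-1]

    J, head_grads = softmax_cost(net.head, top, labels)

    q = X.shape[0]
    probs = softmax_probabilities(net.head, top)
    onehot = np.zeros_like(probs)
    onehot[np.arange(q), labels] = 1.0
    d_top = ((probs - onehot) / q) @ net.head.W  # (q, top_dim)

    grads: dict[tuple, dict[str, np.ndarray]] = {("head",): head_grads}
    delta = d_top
    for li in range(len(net.joint) - 1, -1, -1):
        layer, a_in, a_out = net.joint[li], acts_joint[li], acts_joint[li + 1]
        dz = delta * a_out * (1 - a_out)
        grads[("joint", li)] = {"W_e": dz.T @ a_in, "b_e": dz.sum(axis=0)}
        delta = dz @ layer.W_e
    # split the concat gradient back into the branches
    offset = 0
    for bi, stack in enumerate(net.branches):
        width = stack[-1].n_hidden
        d = delta[:, offset : offset + width]
        offset += width
        acts = acts_branches[bi]
        for li in range(len(stack) - 1, -1, -1):
            layer, a_in, a_out = stack[li], acts[li], acts[li + 1]
            dz = d * a_out * (1 - a_out)
            grads[("branch", bi, li)] = {"W_e": dz.T @ a_in, "b_e": dz.sum(axis=0)}
            d = dz @ layer.W_e
    return J, grads




def _pack(net: _Network) -> np.ndarray:
    parts = [net.head.W.ravel(), net.head.b]
    for layer in net.joint:
        parts += [layer.W_e.ravel(), layer.b_e]
    for stack in net.branches:
        for layer in stack:
            parts += [layer.W_e.ravel(), layer.b_e]
    return np.concatenate(parts)


def _unpack_into(net: _Network, x: np.ndarray) -> _Network:
    new = _Network(
        net.spec,
        [[layer.copy() for layer in stack] for stack in net.branches],
        [layer.copy() for layer in net.joint],
        SoftmaxHead(net.head.W.copy(), net.head.b.copy()),
    )
    pos = 0

    def take(shape):
        nonlocal pos
        n = int(np.prod(shape))
        out = x[pos : pos + n].reshape(shape)
        pos += n
        return out

    new.head.W = take(new.head.W.shape)
    new.head.b = take(new.head.b.shape)
    for layer in new.joint:
        layer.W_e = take(layer.W_e.shape)
        layer.b_e = take(layer.b_e.shape)
    for stack in new.branches:
        for layer in stack:
            layer.W_e = take(layer.W_e.shape)
            layer.b_e = take(layer.b_e.shape)
    return new


def refine(
    net: _Network, X: np.ndarray, labels: np.ndarray, cfg: TrainConfig | None = None
) -> tuple[_Network, list[float]]:
    """Supervised fine-tuning of all encoder weights plus the head.

    Deterministic full-batch L-BFGS on the cross-entropy (plus the head's
    L2 term); the returned loss never exceeds the starting loss, so
    refinement cannot worsen the pretrain-plus-head model on the
    training objective.
    """
    from scipy.optimize import minimize

    cfg = cfg or TrainConfig(learning_rate=1.0, max_iters=200)
    x0 = _pack(net)

    def fun(x):
        candidate = _unpack_into(net, x)
        J, grads = _refine_cost_grads(candidate, X, labels)
        parts = [grads[("head",)]["W"].ravel(), grads[("head",)]["b"]]
        for li in range(len(candidate.joint)):
            parts += [grads[("joint", li)]["W_e"].ravel(), grads[("joint", li)]["b_e"]]
        for bi, stack in enumerate(candidate.branches):
            for li in range(len(stack)):
                g = grads[("branch", bi, li)]
                parts += [g["W_e"].ravel(), g["b_e"]]
        return J, np.concatenate(parts)

    J0 = fun(x0)[0]
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", options={"maxiter": cfg.max_iters})
    if np.isnan(res.fun):
        raise TrainingError("refine cost diverged to NaN")
    if res.fun <= J0:
        best = _unpack_into(net, res.x)
        return best, [J0, float(res.fun)]
    return net, [J0, J0]


# --------------------------------------------------------------------------
# Model / Results


class HelpRequestSAE:
    """Multimodal help-requirement classifier (model object).

    Parameters
    ----------
    motion : ndarray, shape (n, 200)
        Motion features scaled to [0, 1].
    mental : ndarray, shape (n, 80)
        Mental (EEG) features scaled to [0, 1].
    labels : sequence of str or int, length n
        Help-requirement class per record.
    architecture : str
        One of ``single_modal_skeleton``, ``single_modal_eeg``,
        ``early_fusion``, ``late_fusion``.
    """

    def __init__(self, motion, mental, labels, architecture="late_fusion", spec=None):
        self.motion = np.atleast_2d(np.asarray(motion, dtype=float))
        self.mental = np.atleast_2d(np.asarray(mental, dtype=float))
        labels = np.asarray(labels)
        if not (len(self.motion) == len(self.mental) == len(labels)):
            raise InputError("motion, mental and labels must have equal lengths")
        if len(labels) == 0:
            raise InputError("empty training set")
        for M in (self.motion, self.mental):
            if M.size and (M.min() < -1e-9 or M.max() > 1 + 1e-9):
                raise InputError("features must be scaled to [0, 1] before fitting")
        self.classes_ = np.array(sorted(set(labels.tolist())))
        self._y = np.searchsorted(self.classes_, labels)
        self.spec = spec or ArchitectureSpec.default(
            architecture, self.motion.shape[1], self.mental.shape[1]
        )
        self.spec.validate()

    @classmethod
    def from_dataframe(cls, df, label_col="label", architecture="late_fusion"):
        """Build from a DataFrame with ``m000..m199``, ``e000..e079`` columns."""
        motion_cols = [c for c in df.columns if c.startswith("m")]
        mental_cols = [c for c in df.columns if c.startswith("e")]
        return cls(
            df[motion_cols].to_numpy(float),
            df[mental_cols].to_numpy(float),
            df[label_col].to_numpy(),
            architecture,
        )

    def _model_input(self, motion, mental) -> np.ndarray:
        kind = self.spec.kind
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        mental = np.atleast_2d(np.asarray(mental, dtype=float))
        if kind == "single_modal_skeleton":
            return motion
        if kind == "single_modal_eeg":
            return mental
        return np.concatenate([motion, mental], axis=1)

    def fit(
        self,
        sparsity: SparsityConfig | None = None,
        pretrain: TrainConfig | None = None,
        head: TrainConfig | None = None,
        refine_cfg: TrainConfig | None = None,
        refine_iters: int | None = None,
        seed: int = 0,
    ) -> "SAEResults":
        """Two-stage training: greedy unsupervised pretraining, then a
        softmax head and supervised refinement through all encoders.

        ``refine_iters=0`` skips the refinement, leaving the head-only
        model on pretrained features.
        """
        sparsity = sparsity or SparsityConfig()
        pretrain = pretrain or TrainConfig(learning_rate=0.5, max_iters=400, seed=seed)
        head = head or TrainConfig(learning_rate=1.0, max_iters=300, seed=seed)
        if refine_cfg is None:
            refine_cfg = TrainConfig(learning_rate=1.0, max_iters=200, seed=seed)
        if refine_iters is not None:
            refine_cfg = TrainConfig(refine_cfg.learning_rate, refine_iters, seed)

        X = self._model_input(self.motion, self.mental)
        net = _Network(self.spec)
        pretrain_costs = []
        for bi, (sl, sizes) in enumerate(
            zip(self.spec.input_slices(), self.spec.branch_sizes)
        ):
            cfg = TrainConfig(pretrain.learning_rate, pretrain.max_iters, seed + 100 * bi)
            stack = sae.pretrain_stack(X[:, sl], list(sizes), sparsity, cfg)
            net.branches.append(stack)
            pretrain_costs.append([s.cost_trace[-1] if s.cost_trace else None for s in stack])
        H = np.concatenate(
            [
                sae.encode_stack(X[:, sl], stack)
                for sl, stack in zip(self.spec.input_slices(), net.branches)
            ],
            axis=1,
        )
        if self.spec.joint_sizes:
            cfg = TrainConfig(pretrain.learning_rate, pretrain.max_iters, seed + 1000)
            net.joint = sae.pretrain_stack(H, list(self.spec.joint_sizes), sparsity, cfg)
        top = sae.encode_stack(H, net.joint)

        net.head, head_trace = train_softmax_head(top, self._y, len(self.classes_), head)
        if refine_cfg.max_iters > 0:
            net, refine_trace = refine(net, X, self._y, refine_cfg)
        else:
            refine_trace = [head_trace[-1]]
        return SAEResults(self, net, pretrain_costs, head_trace, refine_trace)


class SAEResults:
    """Fitted classifier: parameters, diagnostics, prediction, summary."""

    def __init__(self, model, net, pretrain_costs, head_trace, refine_trace):
        self.model = model
        self.net = net
        self.classes_ = model.classes_
        self.pretrain_costs = pretrain_costs
        self.head_trace = head_trace
        self.refine_trace = refine_trace
        probs = net.probabilities(model._model_input(model.motion, model.mental))
        pred = probs.argmax(axis=1)
        self.train_accuracy = float((pred == model._y).mean())
        self.final_loss = float(refine_trace[-1])

    def predict_proba(self, motion, mental) -> np.ndarray:
        X = self.model._model_input(motion, mental)
        return self.net.probabilities(X)

    def predict(self, motion, mental):
        """Labels with ties broken toward the lowest class index."""
        probs = np.atleast_2d(self.predict_proba(motion, mental))
        labels = self.classes_[probs.argmax(axis=1)]
        single = np.asarray(motion).ndim == 1
        return labels[0] if single else labels

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Help-requirement SAE classifier",
            "=" * 47,
            f"architecture:      {spec.kind}",
            f"records:           {len(self.model._y)}",
            f"classes:           {len(self.classes_)}",
            f"branch sizes:      {spec.branch_sizes}",
            f"joint sizes:       {spec.joint_sizes or '-'}",
            f"pretrain costs:    {[[None if c is None else round(c, 4) for c in b] for b in self.pretrain_costs]}",
            f"head loss:         {self.head_trace[0]:.4f} -> {self.head_trace[-1]:.4f}",
            f"refine loss:       {self.refine_trace[0]:.4f} -> {self.refine_trace[-1]:.4f}",
            f"training accuracy: {100 * self.train_accuracy:.1f}%",
        ]
        return "\n".join(lines)

    def plot_confusion(self, motion=None, mental=None, y=None, ax=None):
        """Confusion-matrix heatmap (training data unless given)."""
        import matplotlib.pyplot as plt

        if motion is None:
            motion, mental = self.model.motion, self.model.mental
            y = self.classes_[self.model._y]
        pred = self.predict(motion, mental)
        k = len(self.classes_)
        idx = {c: i for i, c in enumerate(self.classes_.tolist())}
        conf = np.zeros((k, k), dtype=int)
        for t, p in zip(np.asarray(y), np.asarray(pred)):
            conf[idx[t], idx[p]] += 1
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4.5))
        im = ax.imshow(conf, cmap="Blues")
        ax.set_xticks(range(k), self.classes_, rotation=90)
        ax.set_yticks(range(k), self.classes_)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.figure.colorbar(im, ax=ax)
        return ax
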