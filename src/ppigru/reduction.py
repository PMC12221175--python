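"""Supervised GRU feature reducers, the dimension rule, and ensembling.

Each coding technique's pair vectors (width d) are fed to a gated recurrent
layer as a univariate sequence of d timesteps.  The hidden width per
direction follows the power-of-two rule

    h = 2 ** (floor(log2(d)) - 3)

so a bidirectional reducer emits 2h features.  Reducers are trained for a
few epochs with a single-unit sigmoid head under binary cross-entropy
(Adam, learning rate 1e-3, global-norm gradient clipping at 1); the head is
then discarded and the concatenated final hidden states become the reduced
representation handed to the classifier.

Three ensembling strategies share a 584-wide merged output on the default
lags (8, 7, 9):

* ``multiens`` — six per-technique reducers, rule-derived widths.
* ``multisep`` — one reducer for the three property-profile techniques
  (h=84) and one for the three class-alphabet techniques (h=208).
* ``multicon`` — a single reducer over all six blocks concatenated (h=292).

The grouped widths are fixed constants chosen so all strategies emit
2 x 292 = 584 features, keeping the comparison between strategies
controlled; they are deliberately not rule-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gru
from .gru import F32

TECHNIQUE_ORDER = ("pseaac", "ad", "ac", "ct", "ld", "mmi")

MULTICON_HIDDEN = 292
MULTISEP_HIDDEN = {"profile": 84, "classes": 208}
MULTISEP_GROUPS = {
    "profile": ("pseaac", "ad", "ac"),
    "classes": ("ct", "ld", "mmi"),
}

DIRECTIONS = ("forward", "backward", "bidirectional")


def dimension_rule(d: int) -> int:
    """Hidden width 2**(floor(log2 d) - 3) for a paired input of width d."""
    if d < 16:
        raise ValueError(f"dimension rule undefined for d={d} < 16")
    return 2 ** (int(np.floor(np.log2(d))) - 3)


@dataclass(frozen=True)
class ReducerSpec:
    """Architecture and training hyperparameters of one reducer."""

    input_dim: int
    hidden_dim: int
    direction: str = "bidirectional"
    epochs: int = 5
    learning_rate: float = 1e-3
    clip_norm: float = 1.0
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("input_dim and hidden_dim must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden_dim if self.direction == "bidirectional" else self.hidden_dim

    @classmethod
    def from_rule(cls, input_dim: int, **kw) -> "ReducerSpec":
        return cls(input_dim=input_dim, hidden_dim=dimension_rule(input_dim), **kw)


@dataclass
class ReducedSet:
    """Hidden-state matrix (n_pairs x output width) for one reducer/group."""

    technique: str
    hidden_states: np.ndarray
    labels: np.ndarray | None = None
    trained: bool = True


@dataclass
class Reducer:
    """A (Bi)GRU reducer with a discardable sigmoid training head."""

    spec: ReducerSpec
    cells: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    head_w: np.ndarray | None = None
    head_b: np.ndarray | None = None
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)
    _scratch: dict = field(default_factory=dict, repr=False)

    # -- parameter plumbing -------------------------------------------------

    def _param_list(self) -> list[np.ndarray]:
        out = []
        for d in sorted(self.cells):
            for k in ("W", "b", "U", "c"):
                out.append(self.cells[d][k])
        out.extend([self.head_w, self.head_b])
        return out

    def _directions(self) -> list[str]:
        if self.spec.direction == "bidirectional":
            return ["fwd", "bwd"]
        return ["fwd" if self.spec.direction == "forward" else "bwd"]

    # -- forward ------------------------------------------------------------

    def _hidden(self, X: np.ndarray, keep_cache: bool = False):
        """Concatenated final hidden states for a batch (batch x T)."""
        Xf = X.astype(F32)
        B, T = Xf.shape
        parts, caches = [], {}
        for d in self._directions():
            Xd = Xf if d == "fwd" else Xf[:, ::-1]
            buf = None
            if keep_cache:  # reuse BPTT scratch across batches and epochs
                key = (d, B)
                if key not in self._scratch:
                    self._scratch[key] = gru.make_cache(T, B, self.spec.hidden_dim)
                buf = self._scratch[key]
            hT, cache = gru.cell_forward(self.cells[d], np.ascontiguousarray(Xd),
                                         keep_cache=keep_cache, cache=buf)
            parts.append(hT)
            caches[d] = cache
        return np.concatenate(parts, axis=1), caches

    def transform(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Hidden states for a full matrix, head discarded."""
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected n x {self.spec.input_dim} input, got {X.shape}"
            )
        outs = [
            self._hidden(X[i : i + batch_size])[0]
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0).astype(np.float64)


def build_reducer(spec: ReducerSpec) -> Reducer:
    """Initialize all parameters from ``spec.seed`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    red = Reducer(spec=spec)
    for d in red._directions():
        red.cells[d] = gru.init_cell(spec.hidden_dim, rng)
    k = 1.0 / np.sqrt(spec.output_dim)
    red.head_w = rng.uniform(-k, k, size=spec.output_dim).astype(F32)
    red.head_b = rng.uniform(-k, k, size=1).astype(F32)
    return red


def train_reducer(reducer: Reducer, pairs: np.ndarray, labels: np.ndarray) -> Reducer:
    """Train in place for ``spec.epochs`` epochs; returns the reducer.

    Mini-batch Adam on binary cross-entropy through the sigmoid head, with
    global-norm gradient clipping over all parameters.  The per-epoch mean
    loss is appended to ``loss_history``.
    """
    spec = reducer.spec
    X = np.asarray(pairs)
    y = np.asarray(labels).astype(np.float64).ravel()
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(f"expected n x {spec.input_dim} input, got {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError("pairs/labels length mismatch")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("labels must be binary")
    if uniq.size < 2:
        raise ValueError("training requires both classes present")

    params = reducer._param_list()
    opt = gru.Adam(params, lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    n = X.shape[0]
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, spec.batch_size):
            idx = order[s : s + spec.batch_size]
            Xb, yb = X[idx], y[idx]
            hcat, caches = reducer._hidden(Xb, keep_cache=True)
            logits = hcat @ reducer.head_w + reducer.head_b
            p = gru.sigmoid(logits.astype(np.float64))
            loss, dp = gru.bce_loss_and_grad(p, yb)
            losses.append(loss * idx.size)
            sig_grad = (p * (1.0 - p)).astype(F32)
            dlogit = dp * sig_grad
            g_head_w = hcat.T @ dlogit
            g_head_b = np.array([dlogit.sum()], dtype=F32)
            d_hcat = np.outer(dlogit, reducer.head_w)
            grads: list[np.ndarray] = []
            h = spec.hidden_dim
            dirs = reducer._directions()
            cell_grads = {}
            for j, d in enumerate(dirs):
                cell_grads[d] = gru.cell_backward(
                    reducer.cells[d], caches[d], d_hcat[:, j * h : (j + 1) * h]
                )
            for d in sorted(reducer.cells):
                for k in ("W", "b", "U", "c"):
                    grads.append(cell_grads[d][k])
            grads.extend([g_head_w, g_head_b])
            gru.clip_global_norm(grads, spec.clip_norm)
            opt.step(grads)
        reducer.loss_history.append(sum(losses) / n)
    reducer.trained = True
    reducer._scratch.clear()  # release BPTT buffers (can be ~GB for wide cells)
    return reducer


def extract_hidden(
    reducer: Reducer, pairs: np.ndarray, technique: str = "",
    labels: np.ndarray | None = None,
) -> ReducedSet:
    """Hidden states for ``pairs`` with the training head discarded.

    An untrained reducer still yields a valid (random-projection) output;
    the returned set's ``trained`` flag records which case applies.
    """
    H = reducer.transform(np.asarray(pairs))
    return ReducedSet(technique, H, labels=labels, trained=reducer.trained)


def _merge(sets: list[ReducedSet], labels: np.ndarray) -> ReducedSet:
    H = np.concatenate([s.hidden_states for s in sets], axis=1)
    return ReducedSet("merged", H, labels=labels,
                      trained=all(s.trained for s in sets))


def _check_alignment(blocks: dict[str, np.ndarray], labels: np.ndarray) -> int:
    ns = {t: b.shape[0] for t, b in blocks.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(f"pair-row misalignment across blocks: {ns}")
    n = next(iter(ns.values()))
    if labels.shape[0] != n:
        raise ValueError("labels length does not match block rows")
    return n


def _train_and_apply(spec: ReducerSpec, X_train, y_train, X_apply):
    red = train_reducer(build_reducer(spec), X_train, y_train)
    return red, red.transform(X_apply)


def reduce_multiens(
    blocks: dict[str, np.ndarray],
    labels: np.ndarray,
    seeds: dict[str, int] | int = 0,
    direction: str = "bidirectional",
    epochs: int = 5,
    train_index: np.ndarray | None = None,
    apply_to: np.ndarray | None = None,
) -> tuple[ReducedSet, dict[str, Reducer]]:
    """Six independent reducers (rule widths), hidden states concatenated.

    ``train_index`` restricts supervised training to a row subset (the
    cross-validation training split); extraction runs on ``apply_to`` rows
    (default: all rows).  Merged width is 2 x (4+64+16+64+128+16) = 584 on
    the default lags.
    """
    labels = np.asarray(labels)
    _check_alignment(blocks, labels)
    tr = slice(None) if train_index is None else train_index
    ap = slice(None) if apply_to is None else apply_to
    sets, reducers = [], {}
    for i, tech in enumerate(TECHNIQUE_ORDER):
        if tech not in blocks:
            continue
        X = blocks[tech]
        seed = seeds[tech] if isinstance(seeds, dict) else seeds + i
        spec = ReducerSpec.from_rule(X.shape[1], direction=direction,
                                     epochs=epochs, seed=seed)
        red, H = _train_and_apply(spec, X[tr], labels[tr], X[ap])
        reducers[tech] = red
        sets.append(ReducedSet(tech, H))
    return _merge(sets, labels[ap]), reducers


def reduce_multicon(
    blocks: dict[str, np.ndarray],
    labels: np.ndarray,
    seed: int = 0,
    direction: str = "bidirectional",
    epochs: int = 5,
    hidden_dim: int = MULTICON_HIDDEN,
    train_index: np.ndarray | None = None,
    apply_to: np.ndarray | None = None,
) -> tuple[ReducedSet, dict[str, Reducer]]:
    """All six blocks column-concatenated into a single reducer (h=292)."""
    labels = np.asarray(labels)
    _check_alignment(blocks, labels)
    X = np.concatenate([blocks[t] for t in TECHNIQUE_ORDER if t in blocks], axis=1)
    tr = slice(None) if train_index is None else train_index
    ap = slice(None) if apply_to is None else apply_to
    spec = ReducerSpec(input_dim=X.shape[1], hidden_dim=hidden_dim,
                       direction=direction, epochs=epochs, seed=seed)
    red, H = _train_and_apply(spec, X[tr], labels[tr], X[ap])
    return ReducedSet("multicon", H, labels=labels[ap]), {"all": red}


def reduce_multisep(
    blocks: dict[str, np.ndarray],
    labels: np.ndarray,
    seeds: dict[str, int] | int = 0,
    direction: str = "bidirectional",
    epochs: int = 5,
    train_index: np.ndarray | None = None,
    apply_to: np.ndarray | None = None,
) -> tuple[ReducedSet, dict[str, Reducer]]:
    """Two group reducers: property-profile blocks (h=84), class blocks (h=208)."""
    labels = np.asarray(labels)
    _check_alignment(blocks, labels)
    tr = slice(None) if train_index is None else train_index
    ap = slice(None) if apply_to is None else apply_to
    sets, reducers = [], {}
    for i, (group, techs) in enumerate(MULTISEP_GROUPS.items()):
        X = np.concatenate([blocks[t] for t in techs if t in blocks], axis=1)
        seed = seeds[group] if isinstance(seeds, dict) else seeds + i
        spec = ReducerSpec(input_dim=X.shape[1], hidden_dim=MULTISEP_HIDDEN[group],
                           direction=direction, epochs=epochs, seed=seed)
        red, H = _train_and_apply(spec, X[tr], labels[tr], X[ap])
        reducers[group] = red
        sets.append(ReducedSet(group, H))
    return _merge(sets, labels[ap]), reducers


REDUCE_STRATEGIES = {
    "multiens": reduce_multiens,
    "multicon": reduce_multicon,
    "multisep": reduce_multisep,
}


def save_reducer(reducer: Reducer, path) -> None:
    """Persist parameters + spec as a versioned .npz archive."""
    arrays = {"__version__": np.array([1])}
    for d, cell in reducer.cells.items():
        for k, v in cell.items():
            arrays[f"cell_{d}_{k}"] = v
    arrays["head_w"] = reducer.head_w
    arrays["head_b"] = reducer.head_b
    arrays["trained"] = np.array([int(reducer.trained)])
    arrays["loss_history"] = np.array(reducer.loss_history)
    s = reducer.spec
    arrays["spec"] = np.array(
        [s.input_dim, s.hidden_dim, DIRECTIONS.index(s.direction), s.epochs,
         s.batch_size, s.seed], dtype=np.int64
    )
    arrays["spec_f"] = np.array([s.learning_rate, s.clip_norm])
    np.savez(path, **arrays)


def load_reducer(path) -> Reducer:
    with np.load(path) as z:
        si = z["spec"]
        sf = z["spec_f"]
        spec = ReducerSpec(
            input_dim=int(si[0]), hidden_dim=int(si[1]),
            direction=DIRECTIONS[int(si[2])], epochs=int(si[3]),
            batch_size=int(si[4]), seed=int(si[5]),
            learning_rate=float(sf[0]), clip_norm=float(sf[1]),
        )
        red = Reducer(spec=spec)
        for d in red._directions():
            red.cells[d] = {k: z[f"cell_{d}_{k}"] for k in ("W", "b", "U", "c")}
        red.head_w = z["head_w"]
        red.head_b = z["head_b"]
        red.trained = bool(z["trained"][0])
        red.loss_history = list(z["loss_history"])
    return red
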