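"""Per-muscle geometry surrogates: dataset generation, training,
evaluation and persistence.

The pipeline mirrors how a full-model workflow replaces an external,
non-differentiable geometry engine: draw scaled model variants with
dimension factors from U(0.8, 1.2), sample poses uniformly in the joint
ranges, record muscle-tendon lengths and moment arms, and fit one small
tanh network per muscle (two hidden layers, width 8/12/16 for muscles
spanning 1/2/>=3 coordinates) on z-scored inputs and outputs.  At run
time the network's length head provides muscle-tendon velocity through
the chain rule, ldot_mt = (d l_mt / d q) qdot, while the moment-arm
heads feed the torque mapping.

Per-muscle sample counts default to one tenth of the full-scale
protocol (2,000 / 8,200 / 20,000) to match the bundled desk model;
the full-scale counts are a configuration choice away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .geometry import AnalyticGeometry
from .model import Morphology, MusculoskeletalModel
from .nn import MLP, train_mlp

__all__ = [
    "GeometryDataset",
    "GeometrySurrogate",
    "generate_geometry_dataset",
    "train_surrogate",
    "train_all_surrogates",
    "surrogate_eval",
    "save_surrogates",
    "load_surrogates",
    "SAMPLES_BY_ARITY",
    "WIDTH_BY_ARITY",
]

# samples per muscle by number of spanned coordinates (desk scale, 1/10)
SAMPLES_BY_ARITY = {1: 2000, 2: 8200, 3: 20000}
WIDTH_BY_ARITY = {1: 8, 2: 12, 3: 16}
PS_RANGE = (0.8, 1.2)


def _arity_value(table, n):
    return table[min(n, 3)]


@dataclass
class GeometryDataset:
    """Per-muscle training tables plus provenance metadata."""

    model_name: str
    seed: int
    n_models: int
    # muscle -> dict(X=(n, n_in), Y=(n, 1+n_spanned), columns metadata)
    tables: dict = field(default_factory=dict)

    def n_samples(self, muscle: str) -> int:
        return self.tables[muscle]["X"].shape[0]


def _muscle_inputs(model: MusculoskeletalModel, muscle):
    """(spanned coordinate indices, relevant scaling groups) for one muscle.

    Only the scale factors of segments the muscle's path touches or
    crosses enter its surrogate, mirroring the locality of muscle
    paths: the attachment segments plus every segment on the kinematic
    chain between consecutive path points (their dimensions scale the
    joint offsets the path spans).
    """
    from .kinematics import PlanarKinematics

    kin = PlanarKinematics(model)
    coords = [model.coord_index(c) for c in muscle.spanned_coordinates]

    def chain_to_root(si):
        out = [si]
        while kin.parent[si] >= 0:
            si = kin.parent[si]
            out.append(si)
        return out

    segs: list[int] = []
    pts = [model._seg_index[s] for s, _ in muscle.path.points]
    for a, b in zip(pts[:-1], pts[1:]):
        ca, cb = chain_to_root(a), chain_to_root(b)
        common = next(s for s in ca if s in cb)
        for s in ca[: ca.index(common) + 1] + cb[: cb.index(common)]:
            if s not in segs:
                segs.append(s)
    groups = []
    for si in segs:
        g = model.segments[si].scaling_group
        if g not in groups:
            groups.append(g)
    return coords, groups


def generate_geometry_dataset(model: MusculoskeletalModel, n_models: int = 200,
                              seed: int = 0, samples_by_arity=None) -> GeometryDataset:
    """Sample (p_s, q) -> (l_mt, moment arms) tables for every muscle."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not model.muscles:
        raise ValueError("model has no muscles")
    samples_by_arity = samples_by_arity or SAMPLES_BY_ARITY
    rng = np.random.default_rng(seed)
    from .geometry_fast import FastGeometry
    from .model import _scale_inertial
    fgeo = FastGeometry(model)
    groups = model.scaling_groups()
    # the library of scaled "models": p_s draws per scaling group
    ps_draws = rng.uniform(*PS_RANGE, size=(n_models, len(groups), 3))
    rom = model.rom_bounds()
    q_lb = np.array([rom[c][0] for c in model.coordinates])
    q_ub = np.array([rom[c][1] for c in model.coordinates])
    ds = GeometryDataset(model_name=model.name, seed=seed, n_models=n_models)
    # draw all samples, then evaluate grouped by model for vectorization
    draws = {}
    for muscle in model.muscles:
        coords, rel_groups = _muscle_inputs(model, muscle)
        n = _arity_value(samples_by_arity, len(coords))
        draws[muscle.name] = {
            "coords": coords, "groups": rel_groups,
            "pick": rng.integers(0, n_models, size=n),
            "q": rng.uniform(q_lb, q_ub, size=(n, model.n_coordinates)),
            "lmt": np.empty(n), "R": np.empty((n, len(coords))),
        }
    mi_of = {m.name: i for i, m in enumerate(model.muscles)}
    for im in range(n_models):
        morph = Morphology(p_s={g: ps_draws[im, i] for i, g in enumerate(groups)},
                           p_v=np.ones(model.n_muscles))
        offsets = _scale_inertial(model, morph)[3]
        # union batch of this model's q draws across muscles
        rows, qs = [], []
        for name, d in draws.items():
            sel = np.nonzero(d["pick"] == im)[0]
            rows.append((name, sel, len(qs) and sum(len(q) for _, q in qs)))
            qs.append((sel, d["q"][sel]))
        qb = np.concatenate([q for _, q in qs], axis=0)
        if not len(qb):
            continue
        lmt, R, _ = fgeo.eval(qb, ps_draws[im], offsets)
        start = 0
        for (name, sel, _), (_, qq) in zip(rows, qs):
            d = draws[name]
            sl = slice(start, start + len(sel))
            d["lmt"][sel] = lmt[sl, mi_of[name]]
            d["R"][sel] = R[sl, mi_of[name]][:, d["coords"]]
            start += len(sel)
    for muscle in model.muscles:
        d = draws[muscle.name]
        coords, rel_groups = d["coords"], d["groups"]
        gi = [groups.index(g) for g in rel_groups]
        X = np.concatenate(
            [d["q"][:, coords], ps_draws[d["pick"]][:, gi, :].reshape(len(d["q"]), -1)],
            axis=1)
        Y = np.concatenate([d["lmt"][:, None], d["R"]], axis=1)
        ds.tables[muscle.name] = {
            "X": X, "Y": Y,
            "coords": [model.coordinates[c] for c in coords],
            "groups": rel_groups,
        }
    return ds


@dataclass
class GeometrySurrogate:
    """Trained per-muscle network with normalization constants."""

    muscle: str
    coords: list
    groups: list
    net: MLP
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    holdout_rmse: np.ndarray | None = None  # per output, physical units
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None

    def predict(self, X):
        Xn = (X - self.x_mean) / self.x_std
        return self.net.forward(Xn) * self.y_std + self.y_mean


def train_surrogate(dataset: GeometryDataset, muscle: str, epochs: int = 1000,
                    batch_size: int = 64, seed: int = 0, holdout: float = 0.1,
                    lr: float = 1e-3) -> GeometrySurrogate:
    """Fit one muscle's network; reports held-out RMSE per output."""
    tab = dataset.tables[muscle]
    X, Y = tab["X"], tab["Y"]
    if X.shape[0] == 0:
        raise ValueError(f"dataset empty for muscle {muscle!r}")
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(X.shape[0])
    n_hold = int(round(holdout * X.shape[0]))
    hold, fit = order[:n_hold], order[n_hold:]
    x_mean, x_std = X[fit].mean(0), X[fit].std(0) + 1e-12
    y_mean, y_std = Y[fit].mean(0), Y[fit].std(0) + 1e-12
    Xn = (X - x_mean) / x_std
    Yn = (Y - y_mean) / y_std
    width = _arity_value(WIDTH_BY_ARITY, len(tab["coords"]))
    net = train_mlp(Xn[fit], Yn[fit], hidden=width, epochs=epochs,
                    batch_size=batch_size, seed=seed, lr=lr)
    sur = GeometrySurrogate(
        muscle=muscle, coords=tab["coords"], groups=tab["groups"], net=net,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        x_min=X.min(0), x_max=X.max(0),
    )
    if n_hold:
        pred = sur.predict(X[hold])
        sur.holdout_rmse = np.sqrt(np.mean((pred - Y[hold]) ** 2, axis=0))
    return sur


def train_all_surrogates(dataset: GeometryDataset, epochs: int = 1000,
                         batch_size: int = 64, seed: int = 0, **kw):
    out = {}
    for k, name in enumerate(dataset.tables):
        out[name] = train_surrogate(dataset, name, epochs=epochs,
                                    batch_size=batch_size, seed=seed + 1000 * k, **kw)
    return out


def surrogate_eval(sur: GeometrySurrogate, q_spanned, qdot_spanned, ps_rel,
                   warn_extrapolation: bool = True):
    """(l_mt, ldot_mt, moment arms) from a trained surrogate.

    ``q_spanned``/``qdot_spanned`` are the muscle's spanned coordinates
    (in the surrogate's stored order), ``ps_rel`` the relevant scale
    factors flattened in group order.  Velocity comes from the chain
    rule on the length head; moment arms from the network's dedicated
    outputs.  Differentiable (complex-safe) in every input.
    """
    q_spanned = np.atleast_1d(np.asarray(q_spanned))
    qdot_spanned = np.atleast_1d(np.asarray(qdot_spanned))
    ps_rel = np.atleast_1d(np.asarray(ps_rel))
    X = np.concatenate([q_spanned, ps_rel], axis=-1)
    if warn_extrapolation and sur.x_min is not None and not np.iscomplexobj(X):
        if np.any(X < sur.x_min - 1e-9) or np.any(X > sur.x_max + 1e-9):
            warnings.warn(f"surrogate {sur.muscle}: input outside training domain",
                          stacklevel=2)
    Xn = (X - sur.x_mean) / sur.x_std
    out_n, dl_dxn = sur.net.forward_with_input_grad(Xn[None, :], output_index=0)
    out = out_n[0] * sur.y_std + sur.y_mean
    nq = len(q_spanned)
    dl_dq = dl_dxn[0, :nq] / sur.x_std[:nq] * sur.y_std[0]
    ldot = np.sum(dl_dq * qdot_spanned)
    return out[0], ldot, out[1:]


def excursion_consistency(sur: GeometrySurrogate, X) -> dict:
    """Tendon-excursion consistency of a trained surrogate.

    The analytic fixture satisfies R = -dl/dq exactly; a surrogate's
    moment-arm heads and length-head gradient agree only approximately.
    Returns summary statistics of |R_net + d l_net/d q| over the rows of
    X (m), the metric reported alongside surrogate fidelity.
    """
    X = np.asarray(X, float)
    nq = len(sur.coords)
    Xn = (X - sur.x_mean) / sur.x_std
    out_n, dl_dxn = sur.net.forward_with_input_grad(Xn, output_index=0)
    dl_dq = dl_dxn[:, :nq] / sur.x_std[:nq] * sur.y_std[0]
    arms = out_n[:, 1:] * sur.y_std[1:] + sur.y_mean[1:]
    err = np.abs(arms + dl_dq)
    return {"max": float(err.max()), "mean": float(err.mean()),
            "rms": float(np.sqrt(np.mean(err**2)))}


# -------------------------------------------------------------------------
# persistence
# -------------------------------------------------------------------------


def save_surrogates(surrogates: dict, path):
    with h5py.File(path, "w") as f:
        for name, s in surrogates.items():
            g = f.create_group(name)
            g.attrs["coords"] = [c.encode() for c in s.coords]
            g.attrs["groups"] = [c.encode() for c in s.groups]
            for i, (w, b) in enumerate(zip(s.net.weights, s.net.biases)):
                g.create_dataset(f"w{i}", data=w)
                g.create_dataset(f"b{i}", data=b)
            for key in ("x_mean", "x_std", "y_mean", "y_std", "x_min", "x_max"):
                v = getattr(s, key)
                if v is not None:
                    g.create_dataset(key, data=v)
            if s.holdout_rmse is not None:
                g.create_dataset("holdout_rmse", data=s.holdout_rmse)


def load_surrogates(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            n_layers = sum(1 for k in g if k.startswith("w"))
            net = MLP(
                weights=[g[f"w{i}"][()] for i in range(n_layers)],
                biases=[g[f"b{i}"][()] for i in range(n_layers)],
            )
            out[name] = GeometrySurrogate(
                muscle=name,
                coords=[c.decode() if isinstance(c, bytes) else str(c) for c in g.attrs["coords"]],
                groups=[c.decode() if isinstance(c, bytes) else str(c) for c in g.attrs["groups"]],
                net=net,
                x_mean=g["x_mean"][()], x_std=g["x_std"][()],
                y_mean=g["y_mean"][()], y_std=g["y_std"][()],
                holdout_rmse=g["holdout_rmse"][()] if "holdout_rmse" in g else None,
                x_min=g["x_min"][()] if "x_min" in g else None,
                x_max=g["x_max"][()] if "x_max" in g else None,
            )
    return out
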