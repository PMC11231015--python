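"""Probabilistic coarse-to-fine point-cloud completion.

Two cooperating stages, trained end to end:

* a **probabilistic modeling stage**: permutation-invariant point encoders
  map the partial cloud to a global feature and a diagonal-Gaussian *prior*
  over a latent shape code, and (during training only) the complete cloud to
  a *posterior*; a decoder turns (latent, global feature) into a coarse
  completion. The KL divergence between posterior and prior distills the
  complete-shape information into the prior path.
* a **relational refinement stage**: multi-scale neighborhood self-attention
  over the concatenation of the partial input and the coarse completion
  predicts residual offsets, preserving observed detail while filling in the
  occluded side.

Inference is a MAP point estimate: the prior mean is decoded (no sampling),
so completion is deterministic. The loss is
``kl_weight · KL(q‖p) + CD(coarse, gt) + CD(fine, gt)`` with squared-distance
Chamfer terms on normalized clouds.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor
from .geometry_io import (
    PointCloud,
    denormalize_cloud,
    farthest_point_indices,
    normalize_cloud,
)

__all__ = [
    "LatentDist",
    "TrainingPair",
    "CompletionResult",
    "ModelConfig",
    "CompletionModel",
    "kl_divergence",
    "composite_loss",
    "train",
    "complete",
    "PRESETS",
]

LOGVAR_RANGE = (-10.0, 10.0)


@dataclass
class LatentDist:
    """Diagonal Gaussian in latent space; fields may be numpy or Tensor."""

    mean: Tensor
    log_var: Tensor

    def __post_init__(self) -> None:
        if not isinstance(self.mean, Tensor):
            self.mean = Tensor(np.asarray(self.mean, dtype=np.float64))
        if not isinstance(self.log_var, Tensor):
            self.log_var = Tensor(np.asarray(self.log_var, dtype=np.float64))
        if not (np.all(np.isfinite(self.mean.value)) and np.all(np.isfinite(self.log_var.value))):
            raise ValueError("latent distribution has non-finite entries")

    @property
    def dim(self) -> int:
        return self.mean.value.shape[-1]


@dataclass
class TrainingPair:
    """Normalized partial/complete cloud pair with its denormalization."""

    partial: PointCloud
    complete: PointCloud
    transform: tuple[np.ndarray, float]
    level: str = "L1"
    spine_id: int = 0
    neutral_posture: bool = True

    def __post_init__(self) -> None:
        for name, pc in (("partial", self.partial), ("complete", self.complete)):
            r = np.linalg.norm(pc.points, axis=1).max()
            if r > 1.1:
                raise ValueError(f"{name} cloud extends to {r:.3f}, outside unit sphere + 10%")


@dataclass
class CompletionResult:
    """Coarse and refined completions, denormalized back to mm."""

    coarse: PointCloud
    fine: PointCloud
    transform: tuple[np.ndarray, float]


@dataclass(frozen=True)
class ModelConfig:
    n_in: int = 2048
    n_coarse: int = 512
    n_out: int = 2048
    latent_dim: int = 64
    feature_dim: int = 1024
    attention_scales: tuple[int, ...] = (8, 16)
    kl_weight: float = 0.5
    seed: int = 0
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-4
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        for name in ("n_in", "n_coarse", "n_out", "latent_dim", "feature_dim",
                     "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


PRESETS: dict[str, ModelConfig] = {
    "paper": ModelConfig(),
    "smoke": ModelConfig(
        n_in=256, n_coarse=128, n_out=256, latent_dim=16, feature_dim=64,
        attention_scales=(4, 8), epochs=30, batch_size=8, learning_rate=1e-3,
    ),
}


# ---------------------------------------------------------------------------
# Parameter initialization and primitive layers
# ---------------------------------------------------------------------------


def _dense_init(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    scale = np.sqrt(2.0 / n_in)
    return rng.normal(scale=scale, size=(n_in, n_out)), np.zeros(n_out)


def _dense(params: dict[str, Tensor], name: str, x: Tensor) -> Tensor:
    return x @ params[f"{name}.W"] + params[f"{name}.b"]


def _point_mlp(params: dict[str, Tensor], prefix: str, x: Tensor, dims: list[int]) -> Tensor:
    """Shared per-point MLP on a (B, P, C) tensor."""
    B, P, _ = x.shape
    h = x.reshape(B * P, x.shape[2])
    for i in range(len(dims)):
        h = _dense(params, f"{prefix}.{i}", h)
        if i < len(dims) - 1:
            h = h.relu()
    return h.reshape(B, P, dims[-1])


class CompletionModel:
    """Dual-path variational completion network (numpy parameters)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        F, L = config.feature_dim, config.latent_dim

        def add_mlp(prefix: str, dims: list[int]) -> None:
            for i, (a, b) in enumerate(zip(dims, dims[1:])):
                W, bias = _dense_init(rng, a, b)
                self.params[f"{prefix}.{i}.W"] = Tensor(W, requires_grad=True)
                self.params[f"{prefix}.{i}.b"] = Tensor(bias, requires_grad=True)

        # partial-cloud encoder -> global feature + prior heads
        self._enc_dims = [64, 128, F]
        add_mlp("enc_p", [3] + self._enc_dims)
        add_mlp("prior_mean", [F, L])
        add_mlp("prior_logvar", [F, L])
        # complete-cloud encoder -> posterior heads (training only)
        add_mlp("enc_c", [3] + self._enc_dims)
        add_mlp("post_mean", [F, L])
        add_mlp("post_logvar", [F, L])
        # coarse decoder
        self._dec_hidden = max(256, F // 2)
        add_mlp("dec", [L + F, self._dec_hidden, config.n_coarse * 3])
        # refinement stage
        C = 64
        self._ref_feat = C
        add_mlp("ref_feat", [3, C, C])
        Ca = 32
        self._ref_attn = Ca
        for s, _k in enumerate(config.attention_scales):
            add_mlp(f"attn{s}_q", [C, Ca])
            add_mlp(f"attn{s}_k", [C, Ca])
            add_mlp(f"attn{s}_v", [C, Ca])
        in_ref = 3 + C + Ca * len(config.attention_scales) + C
        add_mlp("ref_out", [in_ref, 128, 3])

    # -- encoders -------------------------------------------------------------

    def _encode(self, cloud: np.ndarray, enc: str, mean_head: str, var_head: str
                ) -> tuple[Tensor, LatentDist]:
        x = np.asarray(cloud, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.n_in:
            raise ValueError(
                f"expected clouds of {self.config.n_in} points, got {x.shape[1]}"
            )
        h = _point_mlp(self.params, enc, Tensor(x), self._enc_dims)
        g = h.max(axis=1)  # permutation-invariant global feature
        mean = _dense(self.params, f"{mean_head}.0", g)
        log_var = _dense(self.params, f"{var_head}.0", g).clamp(*LOGVAR_RANGE)
        return g, LatentDist(mean=mean, log_var=log_var)

    def encode_partial(self, cloud: np.ndarray) -> tuple[Tensor, LatentDist]:
        """Global feature + prior distribution from the observed partial cloud."""
        return self._encode(cloud, "enc_p", "prior_mean", "prior_logvar")

    def encode_complete(self, cloud: np.ndarray) -> LatentDist:
        """Posterior distribution from the complete cloud (training only)."""
        _, dist = self._encode(cloud, "enc_c", "post_mean", "post_logvar")
        return dist

    # -- decoders -------------------------------------------------------------

    def decode_coarse(self, z: Tensor, global_feature: Tensor) -> Tensor:
        """(B, n_coarse, 3) coarse completion from a latent draw + feature."""
        h = Tensor.concatenate([z, global_feature], axis=-1)
        h = _dense(self.params, "dec.0", h).relu()
        out = _dense(self.params, "dec.1", h).tanh() * 1.2
        B = out.shape[0]
        return out.reshape(B, self.config.n_coarse, 3)

    def refine(self, partial: np.ndarray, coarse: Tensor) -> Tensor:
        """Residual multi-scale attention refinement to (B, n_out, 3)."""
        from scipy.spatial import cKDTree

        p = np.asarray(partial, dtype=np.float64)
        if p.ndim == 2:
            p = p[None]
        x = Tensor.concatenate([Tensor(p), coarse], axis=1)  # (B, N, 3)
        B, N, _ = x.shape
        sel = np.unique(np.round(np.linspace(0, N - 1, self.config.n_out)).astype(int))
        if len(sel) < self.config.n_out:  # duplicate tail to hit cardinality
            sel = np.concatenate([sel, sel[: self.config.n_out - len(sel)]])
        sel = np.broadcast_to(sel, (B, self.config.n_out))

        h = _point_mlp(self.params, "ref_feat", x, [self._ref_feat, self._ref_feat])
        x_sel = x.gather(sel)
        h_sel = h.gather(sel)

        feats = [x_sel, h_sel]
        xv = x.value
        for s, k in enumerate(self.config.attention_scales):
            k_eff = min(k, N)
            idx = np.empty((B, self.config.n_out, k_eff), dtype=np.int64)
            for b in range(B):
                tree = cKDTree(xv[b])
                _, nn = tree.query(xv[b][sel[b]], k=k_eff)
                idx[b] = nn.reshape(self.config.n_out, k_eff)
            q = _point_mlp(self.params, f"attn{s}_q", h_sel, [self._ref_attn])
            keys = _point_mlp(self.params, f"attn{s}_k", h, [self._ref_attn]).gather(idx)
            vals = _point_mlp(self.params, f"attn{s}_v", h, [self._ref_attn]).gather(idx)
            qk = (q.reshape(B, self.config.n_out, 1, self._ref_attn) * keys).sum(axis=3)
            attn = (qk * (1.0 / np.sqrt(self._ref_attn))).softmax(axis=2)
            pooled = (attn.reshape(B, self.config.n_out, -1, 1) * vals).sum(axis=2)
            feats.append(pooled)

        g = h.max(axis=1).reshape(B, 1, self._ref_feat) * np.ones((B, self.config.n_out, 1))
        feats.append(g)
        cat = Tensor.concatenate(feats, axis=-1)
        offset = _point_mlp(self.params, "ref_out", cat, [128, 3])
        return x_sel + offset.tanh() * 0.5

    # -- parameter management ---------------------------------------------------

    def parameter_list(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].value = np.asarray(v, dtype=np.float64)

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        meta = {"config": asdict(self.config)}
        if extra:
            meta.update(extra)
        np.savez(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "CompletionModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg = meta["config"]
        cfg["attention_scales"] = tuple(cfg["attention_scales"])
        cfg["split_fractions"] = tuple(cfg["split_fractions"])
        model = cls(ModelConfig(**cfg))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def kl_divergence(q: LatentDist, p: LatentDist) -> Tensor:
    """Closed-form KL(q‖p) between diagonal Gaussians, summed over latent
    dimensions and averaged over any batch axis:

    ½ Σᵢ [ (σq²ᵢ + (μqᵢ − μpᵢ)²) / σp²ᵢ − 1 + ln σp²ᵢ − ln σq²ᵢ ]
    """
    if q.dim != p.dim:
        raise ValueError(f"latent dims differ: {q.dim} vs {p.dim}")
    var_q = q.log_var.exp()
    inv_var_p = (p.log_var * -1.0).exp()
    diff = q.mean - p.mean
    per_dim = (var_q + diff * diff) * inv_var_p - 1.0 + p.log_var - q.log_var
    summed = per_dim.sum(axis=-1) * 0.5
    return summed.mean() if summed.value.ndim else summed


def composite_loss(
    coarse: Tensor,
    fine: Tensor,
    gt: np.ndarray,
    q: LatentDist,
    p: LatentDist,
    kl_weight: float,
) -> tuple[Tensor, dict[str, float]]:
    """KL + coarse and fine Chamfer reconstruction terms (normalized clouds)."""
    gt = np.asarray(gt, dtype=np.float64)
    if gt.ndim == 2:
        gt = gt[None]
    kl = kl_divergence(q, p)
    cd_coarse = coarse.chamfer_to(gt)
    cd_fine = fine.chamfer_to(gt)
    total = kl * kl_weight + cd_coarse + cd_fine
    components = {
        "kl": float(kl.value),
        "cd_coarse": float(cd_coarse.value),
        "cd_fine": float(cd_fine.value),
        "total": float(total.value),
    }
    return total, components


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def split_by_spine(
    pairs: list[TrainingPair],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[int], list[int], list[int]]:
    """Subject-level split: all pairs of one spine land in a single split."""
    spines = sorted({p.spine_id for p in pairs})
    rng = np.random.default_rng(seed)
    rng.shuffle(spines)
    n = len(spines)
    if n >= 3:
        # every split gets at least one subject
        n_train = max(1, min(int(round(fractions[0] * n)), n - 2))
        n_val = max(1, min(int(round(fractions[1] * n)), n - n_train - 1))
    else:
        n_train = max(1, n - 1)
        n_val = n - n_train
    train_ids = set(spines[:n_train])
    val_ids = set(spines[n_train : n_train + n_val])
    test_ids = set(spines[n_train + n_val :])
    by = lambda ids: [i for i, p in enumerate(pairs) if p.spine_id in ids]
    return by(train_ids), by(val_ids), by(test_ids)


def _epoch_loss(model: CompletionModel, P: np.ndarray, G: np.ndarray,
                idx: list[int], kl_weight: float, batch_size: int) -> float:
    """Validation-style loss: posterior mean latent, no sampling, no updates."""
    total, n = 0.0, 0
    for s in range(0, len(idx), batch_size):
        b = idx[s : s + batch_size]
        g, prior = model.encode_partial(P[b])
        post = model.encode_complete(G[b])
        coarse = model.decode_coarse(post.mean, g)
        fine = model.refine(P[b], coarse)
        _, comp = composite_loss(coarse, fine, G[b], post, prior, kl_weight)
        total += comp["total"] * len(b)
        n += len(b)
    return total / max(n, 1)


def train(
    pairs: list[TrainingPair],
    config: ModelConfig,
) -> tuple[CompletionModel, dict]:
    """End-to-end training with a subject-level 60/20/20 split.

    The latent is sampled from the posterior with the reparameterization
    trick; the KL weight ramps linearly over the first 10% of epochs to
    avoid posterior collapse. Returns the model restored to its best
    validation checkpoint and the per-epoch loss history.
    """
    if len(pairs) < 3 * config.batch_size:
        raise ValueError(
            f"need at least {3 * config.batch_size} pairs, got {len(pairs)}"
        )
    tr, va, te = split_by_spine(pairs, config.split_fractions, config.seed)
    if not tr or not va:
        raise ValueError("split produced an empty train or validation set")

    P = np.stack([p.partial.points for p in pairs])
    G = np.stack([p.complete.points for p in pairs])

    model = CompletionModel(config)
    opt = Adam(model.parameter_list(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    warmup = max(1, int(np.ceil(config.epochs * 0.1)))
    history: dict = {"train": [], "val": [], "kl_weight": [],
                     "split": {"train": tr, "val": va, "test": te}}
    best_val, best_state = np.inf, model.state_dict()

    for epoch in range(config.epochs):
        klw = config.kl_weight * min(1.0, (epoch + 1) / warmup)
        order = np.array(tr)
        rng.shuffle(order)
        ep_loss, n_seen = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            b = order[s : s + config.batch_size]
            g, prior = model.encode_partial(P[b])
            post = model.encode_complete(G[b])
            eps = rng.standard_normal(post.mean.shape)
            z = post.mean + (post.log_var * 0.5).exp() * eps
            coarse = model.decode_coarse(z, g)
            fine = model.refine(P[b], coarse)
            loss, comp = composite_loss(coarse, fine, G[b], post, prior, klw)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += comp["total"] * len(b)
            n_seen += len(b)
        val = _epoch_loss(model, P, G, va, config.kl_weight, config.batch_size)
        history["train"].append(ep_loss / n_seen)
        history["val"].append(val)
        history["kl_weight"].append(klw)
        if val < best_val:
            best_val = val
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    history["best_val"] = float(best_val)
    return model, history


# ---------------------------------------------------------------------------
# Smoke benchmark data
# ---------------------------------------------------------------------------


def make_sphere_benchmark(
    n_pairs: int = 200,
    config: ModelConfig = PRESETS["smoke"],
    seed: int = 0,
    cap_cos: float = 0.3,
) -> list[TrainingPair]:
    """Sphere-with-cap-removed pairs for desk-scale learning checks.

    Each ground truth is a mildly anisotropic unit sphere; the partial view
    drops the polar cap ``z/r > cap_cos`` (about a third of the surface),
    mimicking a fixed occluded region the network must hallucinate. One
    synthetic "subject" spans 5 consecutive pairs so the subject-level split
    stays meaningful.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        ax = 1.0 + rng.uniform(-0.25, 0.25, size=3)
        u = rng.normal(size=(4 * config.n_in, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = u * ax
        pts /= np.linalg.norm(pts, axis=1).max()
        gt = pts[: config.n_in]
        visible = pts[pts[:, 2] < cap_cos * np.linalg.norm(pts, axis=1)]
        part = visible[: config.n_in]
        if len(part) < config.n_in:
            pad = rng.choice(len(part), config.n_in - len(part), replace=True)
            part = np.vstack([part, part[pad]])
        pairs.append(
            TrainingPair(
                partial=PointCloud(points=part),
                complete=PointCloud(points=gt),
                transform=(np.zeros(3), 1.0),
                level="L1",
                spine_id=i // 5,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def complete(partial_mm: PointCloud, model: CompletionModel) -> CompletionResult:
    """MAP completion of a partial cloud given in millimeters.

    Normalizes the input, encodes it, decodes the *prior mean* (the MAP
    point estimate — no sampling, so repeated calls are identical), refines,
    and denormalizes both outputs back to mm with the input's transform.
    """
    if len(partial_mm) == 0:
        raise ValueError("empty input cloud")
    normalized, transform = normalize_cloud(partial_mm)
    pts = normalized.points
    n_in = model.config.n_in
    if len(pts) > n_in:
        pts = pts[np.sort(farthest_point_indices(pts, n_in, seed=0))]
    elif len(pts) < n_in:
        reps = np.resize(np.arange(len(pts)), n_in - len(pts))
        pts = np.vstack([pts, pts[reps]])

    g, prior = model.encode_partial(pts)
    coarse = model.decode_coarse(prior.mean, g)
    fine = model.refine(pts[None], coarse)
    coarse_pc = denormalize_cloud(PointCloud(points=coarse.value[0]), transform)
    fine_pc = denormalize_cloud(PointCloud(points=fine.value[0]), transform)
    return CompletionResult(coarse=coarse_pc, fine=fine_pc, transform=transform)
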