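"""Synthetic stand-in for the institutional slide set.

Two generators live here.  ``simulate_feature_table`` draws per-image
feature vectors (avg_R, avg_G, avg_B, entropy) from class-conditional
multivariate Gaussians whose default means and SDs are the reference
cohort's printed summaries, so downstream statistics face data with the
documented class separation.  ``render_image`` goes one level lower and
produces actual RGB pixel rasters whose *extracted* features hit requested
targets: pixels share a latent gray level drawn from a one-parameter
exponential-family distribution over a narrow gray window, giving monotone
(hence solvable) control of histogram entropy, while per-channel integer
offsets set the channel means.

Only the marginal feature distributions are controlled.  Real H&E tiles
have spatial structure (nuclei, stroma, stain texture) that these rasters
do not attempt; every downstream statistic here depends on the histogram
and channel means alone, which is exactly what the rasters reproduce.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.optimize import brentq

from .reference import COHORT_SUMMARY, FEATURES

__all__ = [
    "ClassParams",
    "SimulationConfig",
    "RenderResult",
    "simulate_feature_table",
    "render_image",
    "generate_dataset",
    "load_config",
]

_CHANNEL_FEATURES = ("avg_r", "avg_g", "avg_b")


@dataclass
class ClassParams:
    """Class-conditional feature distribution: mean/SD per feature plus an
    optional 4x4 correlation matrix (identity = independent features)."""

    mean: np.ndarray  # (avg_r, avg_g, avg_b, entropy)
    sd: np.ndarray
    n: int
    corr: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        self.corr = np.asarray(self.corr, dtype=np.float64)
        if self.mean.shape != (4,) or self.sd.shape != (4,):
            raise ValueError("mean and sd must be length-4 vectors")
        # zero SD is allowed as a degenerate (point-mass) distribution
        if np.any(self.sd < 0):
            raise ValueError("SDs must be non-negative")
        if self.n < 1:
            raise ValueError("n per class must be >= 1")

    def validate_corr(self, class_name: str) -> None:
        c = self.corr
        if c.shape != (4, 4):
            raise ValueError(f"{class_name}: correlation matrix must be 4x4")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError(f"{class_name}: correlation matrix not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError(f"{class_name}: correlation diagonal must be 1")
        eigmin = float(np.linalg.eigvalsh(c).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"{class_name}: correlation matrix is not positive "
                f"semi-definite (min eigenvalue {eigmin:.3e})"
            )

    def covariance(self) -> np.ndarray:
        d = np.diag(self.sd)
        return d @ self.corr @ d


def _default_class(name: str, n: int | None = None) -> ClassParams:
    ref = COHORT_SUMMARY[name]
    return ClassParams(
        mean=np.array([ref["mean"][f] for f in FEATURES]),
        sd=np.array([ref["sd"][f] for f in FEATURES]),
        n=n if n is not None else ref["n"],
    )


@dataclass
class SimulationConfig:
    """Generator settings.

    Defaults reproduce the reference cohort: 2,214 malignant and 509 benign
    images with the printed class-conditional means/SDs, independent
    features, and 128x128 rasters over a 64-level gray window.  The window
    width ``window`` caps achievable entropy at log2(window) bits and keeps
    the channel offsets clip-free for means near 220-229.
    """

    benign: ClassParams = field(default_factory=lambda: _default_class("benign"))
    malignant: ClassParams = field(default_factory=lambda: _default_class("malignant"))
    seed: int = 0
    width: int = 128
    height: int = 128
    window: int = 64

    def __post_init__(self) -> None:
        if not (2 <= self.window <= 256):
            raise ValueError("gray window width must lie in [2, 256]")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        for name in ("benign", "malignant"):
            getattr(self, name).validate_corr(name)

    @property
    def max_entropy(self) -> float:
        return float(np.log2(self.window))


def load_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a flat YAML/JSON file.

    Layout: class blocks ``benign:`` / ``malignant:`` each with ``mean_r,
    mean_g, mean_b, mean_h, sd_r, sd_g, sd_b, sd_h, n``; top-level ``seed,
    width, height, window``.  Missing keys fall back to the defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    def class_from(block: dict | None, name: str) -> ClassParams:
        base = _default_class(name)
        if not block:
            return base
        keys = ("r", "g", "b", "h")
        mean = np.array(
            [block.get(f"mean_{k}", base.mean[i]) for i, k in enumerate(keys)]
        )
        sd = np.array(
            [block.get(f"sd_{k}", base.sd[i]) for i, k in enumerate(keys)]
        )
        return ClassParams(mean=mean, sd=sd, n=int(block.get("n", base.n)))

    return SimulationConfig(
        benign=class_from(raw.get("benign"), "benign"),
        malignant=class_from(raw.get("malignant"), "malignant"),
        seed=int(raw.get("seed", 0)),
        width=int(raw.get("width", 128)),
        height=int(raw.get("height", 128)),
        window=int(raw.get("window", 64)),
    )


def simulate_feature_table(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-image feature vectors for both classes.

    Returns a FeatureTable DataFrame (``image_id, label, avg_r, avg_g,
    avg_b, entropy``) with ``n_benign + n_malignant`` rows, benign first.
    Channel features are clipped to [0, 255] and entropy to [0, 8] after
    the Gaussian draw (clip rates are negligible at the default
    parameters).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for label in ("benign", "malignant"):
        params: ClassParams = getattr(config, label)
        params.validate_corr(label)
        # svd factorization tolerates singular (zero-SD) covariance
        x = rng.multivariate_normal(
            params.mean, params.covariance(), size=params.n, method="svd"
        )
        x[:, :3] = np.clip(x[:, :3], 0.0, 255.0)
        x[:, 3] = np.clip(x[:, 3], 0.0, 8.0)
        df = pd.DataFrame(x, columns=list(FEATURES))
        df.insert(0, "label", label)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "image_id", [f"img_{i:06d}" for i in range(len(out))])
    return out


def _window_entropy(lam: float, window: int) -> float:
    """Entropy (bits) of p_g proportional to exp(-lam*g), g in {0..window-1}."""
    g = np.arange(window, dtype=np.float64)
    logits = -lam * g
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    p = p[p > 1e-300]
    return float(-(p * np.log2(p)).sum())


def _solve_gray_distribution(target_h: float, window: int) -> np.ndarray:
    """Gray-level probabilities over {0..window-1} with entropy target_h.

    The family p_g proportional to exp(-lam*g) has entropy log2(window) at
    lam=0, decreasing monotonically to 0 as lam grows; lam is found by
    bisection (Brent).
    """
    if target_h < 0:
        raise ValueError("target entropy must be non-negative")
    max_h = float(np.log2(window))
    if target_h >= max_h:
        raise ValueError(
            f"target entropy {target_h:.3f} not achievable in a "
            f"{window}-level window (max {max_h:.3f} bits)"
        )
    if target_h == 0.0:
        p = np.zeros(window)
        p[0] = 1.0
        return p
    lo, hi = 0.0, 1.0
    while _window_entropy(hi, window) > target_h:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - entropy ~0 handled above
            break
    lam = brentq(lambda l: _window_entropy(l, window) - target_h, lo, hi,
                 xtol=1e-12)
    g = np.arange(window, dtype=np.float64)
    p = np.exp(-lam * g)
    # mirror so the mode sits at the window top: H&E images are bright, so
    # the sparse tail must point down-range to keep offsets clip-free
    return (p / p.sum())[::-1].copy()


@dataclass
class RenderResult:
    """A rendered raster plus bookkeeping from the renderer."""

    image: np.ndarray  # HxWx3 uint8
    clipped: bool  # True when >1% of channel values hit the [0,255] clamp
    clip_fraction: float
    offsets: tuple[int, int, int]


def render_image(
    target: tuple[float, float, float, float],
    width: int = 128,
    height: int = 128,
    window: int = 64,
    seed: int = 0,
) -> RenderResult:
    """Render an RGB raster whose extracted features approximate *target*.

    ``target`` is (avg_r, avg_g, avg_b, entropy).  Every pixel draws one
    latent gray level g i.i.d. from the entropy-matched window distribution;
    channel c is ``g + round(target_c - E[g])`` clipped to [0, 255].  Because
    the three channels differ from g by constants and the luma weights sum
    to one, the grayscale conversion is the latent g shifted by a constant,
    so its histogram entropy equals the latent entropy exactly when nothing
    clips.

    Contract (when ``clipped`` is False): extracted channel means within
    +/-1.0 intensity units of targets; extracted luma entropy within +/-0.1
    bits of the target.  Infeasible targets (offset forcing >1% of values
    onto the clamp) set the ``clipped`` flag instead of raising.
    """
    tr, tg, tb, th = (float(v) for v in target)
    for name, v in (("avg_r", tr), ("avg_g", tg), ("avg_b", tb)):
        if not (0.0 <= v <= 255.0):
            raise ValueError(f"target {name}={v} outside [0, 255]")
    p = _solve_gray_distribution(th, window)
    mean_g = float(np.arange(window) @ p)

    rng = np.random.default_rng(seed)
    g = rng.choice(window, size=(height, width), p=p)

    channels = []
    n_clipped = 0
    offsets = []
    for t in (tr, tg, tb):
        off = int(np.floor(t - mean_g + 0.5))
        offsets.append(off)
        c = g + off
        n_clipped += int(np.count_nonzero((c < 0) | (c > 255)))
        channels.append(np.clip(c, 0, 255))
    image = np.stack(channels, axis=-1).astype(np.uint8)
    clip_fraction = n_clipped / (3 * height * width)
    return RenderResult(
        image=image,
        clipped=clip_fraction > 0.01,
        clip_fraction=clip_fraction,
        offsets=tuple(offsets),
    )


def generate_dataset(config: SimulationConfig, output_dir: str | Path) -> pd.DataFrame:
    """Simulate features, render one PNG per row, and write a manifest CSV.

    Entropy targets above the window's capacity are capped just below
    log2(window) before rendering (the simulated table keeps the uncapped
    value).  Re-running with the same config reproduces a byte-identical
    manifest.  Returns the manifest DataFrame (``image_id, path, label,
    patient_id``; paths relative to *output_dir*).
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc

    table = simulate_feature_table(config)
    seeds = np.random.SeedSequence(config.seed).spawn(len(table))
    h_cap = config.max_entropy - 1e-6
    records = []
    for i, row in enumerate(table.itertuples(index=False)):
        target = (row.avg_r, row.avg_g, row.avg_b, min(row.entropy, h_cap))
        child_seed = int(seeds[i].generate_state(1)[0] % (2**31))
        res = render_image(
            target, config.width, config.height, config.window, seed=child_seed
        )
        fname = f"{row.image_id}.png"
        # deterministic PNG bytes: fixed encoder settings, no metadata
        buf = io.BytesIO()
        Image.fromarray(res.image, mode="RGB").save(buf, format="PNG")
        (out / fname).write_bytes(buf.getvalue())
        records.append(
            {
                "image_id": row.image_id,
                "path": fname,
                "label": row.label,
                "patient_id": "",
            }
        )
    manifest = pd.DataFrame(records, columns=["image_id", "path", "label", "patient_id"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
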