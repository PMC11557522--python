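"""Generative-backend contract and implementations.

Every backend takes a :class:`BackendRequest` — the photograph, the
conditioning bundle (edge image, mask, target contour) and a seed — and
returns a predicted post-operative image in which **pixels outside the mask
are bit-identical to the input**. Three backends are provided:

* ``geometric_warp`` — deterministic per-column vertical resampling that
  maps the original upper-lid curve onto the target contour, decaying to
  zero displacement at the mask boundary. This is the desk-scale reference
  generator: fully self-contained, no weights, exactly reproducible.
* ``ddpm_toy`` — a seeded noise/denoise chain anchored on the warp output
  inside the mask, demonstrating the diffusion sampler contract on real
  rasters. Not a production generator.
* ``controlnet`` — adapter slot delegating to an external edge-conditioned
  inpainting engine (pretrained weights, not bundled); raises a typed
  "backend not installed" error when no engine is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .diffusion import build_schedule, forward_sample, gaussian_eps_estimate, reverse_chain
from .errors import BackendError, BackendNotInstalledError, ConfigurationError
from .targets import ConditioningBundle

__all__ = [
    "BackendRequest",
    "geometric_warp_predict",
    "ddpm_toy_predict",
    "controlnet_inpaint_predict",
    "get_backend",
]


@dataclass
class BackendRequest:
    """One prediction job handed to a generative backend."""

    image: np.ndarray
    bundle: ConditioningBundle
    seed: int = 0
    strength: float = 1.0

    def __post_init__(self) -> None:
        hw = self.image.shape[:2]
        if hw != self.bundle.mask.shape or hw != self.bundle.edge_image.shape:
            raise ConfigurationError("image and bundle rasters differ in dimensions")
        if not (0.0 <= self.strength <= 1.0):
            raise ConfigurationError("strength must lie in [0, 1]")


def _column_curves(request: BackendRequest):
    eye = request.bundle.source_eye
    target = request.bundle.target_contour
    lo = max(eye.upper_lid.x_range[0], target.x_range[0])
    hi = min(eye.upper_lid.x_range[1], target.x_range[1])
    return eye.upper_lid, target, lo, hi


def geometric_warp_predict(request: BackendRequest) -> np.ndarray:
    """Deterministic vertical warp mapping the original lid onto the target.

    Within each masked column, rows are piecewise-linearly resampled so the
    original lid row lands on the target row, with displacement decaying to
    zero at the top and bottom of the mask. Ignores the seed.
    """
    orig, target, lo, hi = _column_curves(request)
    mask = request.bundle.mask
    img = np.asarray(request.image)
    H, W = mask.shape
    out = img.copy()
    flt = img.astype(float)
    rows = np.arange(H, dtype=float)

    for col in range(int(np.ceil(lo)), int(np.floor(hi)) + 1):
        if 0 <= col < W and not mask[:, col].any():
            raise BackendError(
                f"target column {col} is not covered by the inpainting mask"
            )

    for col in range(W):
        colmask = mask[:, col]
        if not colmask.any():
            continue
        sel = np.flatnonzero(colmask)
        rtop, rbot = float(sel.min()), float(sel.max())
        if not (lo <= col <= hi) or rbot - rtop < 2:
            continue  # margin-only column: zero displacement
        y_o = float(np.clip(orig.y_at(col), rtop + 0.5, rbot - 0.5))
        y_t = float(np.clip(target.y_at(col), rtop + 0.5, rbot - 0.5))
        # piecewise-linear map from output row to source row
        src = np.interp(rows[sel], [rtop, y_t, rbot], [rtop, y_o, rbot])
        if img.ndim == 3:
            for c in range(img.shape[2]):
                vals = np.interp(src, rows, flt[:, col, c])
                out[sel, col, c] = _cast_like(vals, img.dtype)
        else:
            vals = np.interp(src, rows, flt[:, col])
            out[sel, col] = _cast_like(vals, img.dtype)
    return out


def _cast_like(vals: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(np.rint(vals), info.min, info.max).astype(dtype)
    return vals.astype(dtype)


def ddpm_toy_predict(request: BackendRequest, T: int = 50) -> np.ndarray:
    """Seeded forward-noise / analytic-denoise chain anchored on the warp output.

    The masked region of the geometric-warp prediction is noised to step
    t* = round(strength * T) and denoised back with the exact Gaussian noise
    estimate centred on the warp output. Deterministic under a fixed seed;
    pixels outside the mask are copied bit-exactly. A demonstration sampler,
    not the production generator.
    """
    anchor = geometric_warp_predict(request)
    mask = request.bundle.mask
    t_star = max(1, int(round(request.strength * T)))
    schedule = build_schedule(T=t_star, beta_start=1e-4, beta_end=0.02)
    rng = np.random.default_rng(request.seed)

    img = np.asarray(anchor)
    flt = img.astype(float) / 255.0 if np.issubdtype(img.dtype, np.integer) else img.astype(float)
    sel = mask if img.ndim == 2 else np.broadcast_to(mask[..., None], img.shape)
    x0 = flt[sel]
    xt = forward_sample(x0, t_star, schedule, rng.standard_normal(x0.shape))
    x_hat = reverse_chain(
        xt,
        schedule,
        lambda x, t: gaussian_eps_estimate(x, t, schedule, mu=x0, sigma0=0.02),  # type: ignore[arg-type]
        rng=rng,
    )
    out_f = flt.copy()
    out_f[sel] = x_hat
    if np.issubdtype(img.dtype, np.integer):
        out = img.copy()
        out[sel] = np.clip(np.rint(out_f[sel] * 255.0), 0, 255).astype(img.dtype)
        return out
    return out_f


class InpaintEngine(Protocol):
    """External edge-conditioned inpainting engine interface."""

    def __call__(
        self,
        image: np.ndarray,
        edge_image: np.ndarray,
        mask: np.ndarray,
        seed: int,
        strength: float,
    ) -> np.ndarray: ...


def controlnet_inpaint_predict(
    request: BackendRequest, engine: InpaintEngine | None = None
) -> np.ndarray:
    """Delegate to an external edge-conditioned inpainting engine.

    The engine (pretrained weights, GPU) is not bundled; without one this
    raises :class:`BackendNotInstalledError` advising the geometric_warp
    backend. Output dimensions are validated against the input.
    """
    if engine is None:
        raise BackendNotInstalledError(
            "no external inpainting engine is installed; use backend "
            "'geometric_warp' for a self-contained prediction"
        )
    out = engine(
        image=request.image,
        edge_image=request.bundle.edge_image,
        mask=request.bundle.mask,
        seed=request.seed,
        strength=request.strength,
    )
    out = np.asarray(out)
    if out.shape != request.image.shape:
        raise BackendError(
            f"engine returned shape {out.shape}, expected {request.image.shape}"
        )
    return out


_BACKENDS: dict[str, Callable[..., np.ndarray]] = {
    "geometric_warp": geometric_warp_predict,
    "ddpm_toy": ddpm_toy_predict,
    "controlnet": controlnet_inpaint_predict,
}


def get_backend(name: str) -> Callable[..., np.ndarray]:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
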