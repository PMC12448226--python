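"""Geographic clines: transect projection and sigmoid-with-tails fitting.

An ancestry proxy measured along a one-dimensional transect is modelled as
a sigmoid transition

    S(x) = 1 / (1 + exp(-4 (x - c) / w))

with centre c (km) and width w (km; the inverse of the maximum slope, so
the slope of the fitted trait at c is (pmax - pmin)/w). Optional
exponential introgression tails start delta km from the centre and decay
with a tail-slope ratio tau in (0, 1]; the five candidate models are the
five tail configurations (none / left / right / mirror / both) with the
trait end values pmin < pmax free. Fitting is random-walk Metropolis under
a Gaussian observation model with homoscedastic residual SD; model choice
is by AICc from the maximum log-likelihood visited; the width support
interval collects every visited w within two log-likelihood units of the
maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _mcmc

EARTH_RADIUS_KM = 6371.0088

TAIL_CONFIGS = ("none", "left", "right", "mirror", "both")


@dataclass
class GeographicClineModel:
    pmin: float
    pmax: float
    c: float
    w: float
    tail_config: str = "none"
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0
    #: False for a cline falling along the transect (the shape is the
    #: mirror image of the rising one; delta/tau keep their x-side meaning)
    ascending: bool = True

    def __post_init__(self) -> None:
        if self.tail_config not in TAIL_CONFIGS:
            raise ValueError(f"unknown tail config {self.tail_config!r}")
        if not (self.pmin < self.pmax):
            raise ValueError("pmin must be < pmax")
        if self.w <= 0:
            raise ValueError("width must be positive")


@dataclass
class GeographicClineFit:
    model: GeographicClineModel
    log_l: float
    aicc: float
    width_interval: tuple[float, float]
    sigma: float
    n_params: int
    draws: dict = field(default_factory=dict)


def project_to_transect(lat, lon, line) -> np.ndarray:
    """Distance (km) of each point along a transect line.

    The line is ((lat1, lon1), (lat2, lon2)). Points are mapped to a local
    equirectangular plane (longitudes scaled by cos of the mean latitude of
    the line, adequate for transects spanning a few degrees), orthogonally
    projected onto the line, and measured from the line's first endpoint.
    Signed: points behind the start get negative distances.
    """
    (lat1, lon1), (lat2, lon2) = line
    if (lat1, lon1) == (lat2, lon2):
        raise ValueError("transect endpoints must be distinct")
    lat_m = math.radians((lat1 + lat2) / 2.0)
    kx = EARTH_RADIUS_KM * math.cos(lat_m) * math.pi / 180.0
    ky = EARTH_RADIUS_KM * math.pi / 180.0
    px = (np.asarray(lon, float) - lon1) * kx
    py = (np.asarray(lat, float) - lat1) * ky
    ux = (lon2 - lon1) * kx
    uy = (lat2 - lat1) * ky
    norm = math.hypot(ux, uy)
    return (px * ux + py * uy) / norm


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance, the projection-free alternative for long lines."""
    rl1, rl2 = math.radians(lat1), math.radians(lat2)
    dlat = rl2 - rl1
    dlon = math.radians(lon2 - lon1)
    a = math.sin(dlat / 2) ** 2 + math.cos(rl1) * math.cos(rl2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def ancestry_proxy(values, idx_p0=None, idx_p1=None) -> np.ndarray:
    """Affinely rescale an ancestry axis so the panel means map to 0 and 1.

    ``values`` is typically PC1 (sign ambiguity is resolved by the
    anchoring) or posterior hybrid indexes. With no anchor indices the
    values pass through unchanged (the hybrid-index path).
    """
    v = np.asarray(values, dtype=float)
    if idx_p0 is None or idx_p1 is None:
        return v
    m0 = v[np.asarray(idx_p0)].mean()
    m1 = v[np.asarray(idx_p1)].mean()
    if m0 == m1:
        raise ValueError("reference panels coincide on the ancestry axis")
    return (v - m0) / (m1 - m0)


def _shape(x: np.ndarray, m: GeographicClineModel) -> np.ndarray:
    """Cline shape on [0, 1] (before the pmin/pmax affine map)."""
    x = np.asarray(x, dtype=float)
    s = 1.0 / (1.0 + np.exp(np.clip(-4.0 * (x - m.c) / m.w, -700, 700)))
    cfg = m.tail_config
    if cfg in ("left", "mirror", "both"):
        dl = m.delta_l
        tl = m.tau_l
        xl = m.c - dl
        s_j = 1.0 / (1.0 + math.exp(min(4.0 * dl / m.w, 700)))
        rate = 4.0 * tl / (m.w * (1.0 + math.exp(-4.0 * dl / m.w)))
        left = x <= xl
        s = np.where(left, s_j * np.exp(np.minimum(rate * (x - xl), 0.0)), s)
    if cfg in ("right", "mirror", "both"):
        dr = m.delta_r if cfg in ("right", "both") else m.delta_l
        tr = m.tau_r if cfg in ("right", "both") else m.tau_l
        xr = m.c + dr
        s_j = 1.0 / (1.0 + math.exp(min(4.0 * dr / m.w, 700)))
        rate = 4.0 * tr / (m.w * (1.0 + math.exp(-4.0 * dr / m.w)))
        right = x >= xr
        s = np.where(right, 1.0 - s_j * np.exp(np.minimum(-rate * (x - xr), 0.0)), s)
    return s


def cline_value(x, model: GeographicClineModel) -> np.ndarray:
    """Expected proxy value at transect position x (km)."""
    if not model.ascending:
        import dataclasses

        mirrored = dataclasses.replace(
            model, ascending=True,
            delta_l=model.delta_r, tau_l=model.tau_r,
            delta_r=model.delta_l, tau_r=model.tau_l,
        )
        return cline_value(2.0 * model.c - np.asarray(x, float), mirrored)
    out = model.pmin + (model.pmax - model.pmin) * _shape(x, model)
    return out if np.ndim(out) else float(out)


def _n_free_params(tail_config: str) -> int:
    # pmin, log-range, c, ln w, ln sigma, plus tail parameters
    base = 5
    return base + {"none": 0, "left": 2, "right": 2, "mirror": 2, "both": 4}[
        tail_config
    ]


def _unpack(theta: np.ndarray, tail_config: str) -> GeographicClineModel:
    pmin = theta[0]
    pmax = pmin + math.exp(theta[1])
    c = theta[2]
    w = math.exp(theta[3])
    kw = {}
    if tail_config == "left":
        kw = {"delta_l": math.exp(theta[5]), "tau_l": _expit(theta[6])}
    elif tail_config == "right":
        kw = {"delta_r": math.exp(theta[5]), "tau_r": _expit(theta[6])}
    elif tail_config == "mirror":
        d, t = math.exp(theta[5]), _expit(theta[6])
        kw = {"delta_l": d, "tau_l": t, "delta_r": d, "tau_r": t}
    elif tail_config == "both":
        kw = {
            "delta_l": math.exp(theta[5]),
            "tau_l": _expit(theta[6]),
            "delta_r": math.exp(theta[7]),
            "tau_r": _expit(theta[8]),
        }
    return GeographicClineModel(pmin, pmax, c, w, tail_config, **kw)


def _expit(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def fit_geographic_cline(
    x,
    proxy,
    tail_config: str = "none",
    burn: int = 3000,
    keep: int = 9000,
    seed: int | None = None,
) -> GeographicClineFit:
    """Metropolis–Hastings fit of one tail configuration.

    Gaussian observation model around :func:`cline_value` with a free
    residual SD. Requires >= 10 samples spanning both sides of the putative
    centre (the proxy midrange crossing). AICc is computed from the maximum
    log-likelihood seen along the chain; the width interval is the range of
    w among visited parameter vectors with log L >= max log L - 2.
    """
    x = np.asarray(x, dtype=float)
    yv = np.asarray(proxy, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(yv) == 0:
        raise ValueError("all proxy values identical; no cline to fit")
    # the shape is rising by convention (pmin < pmax); a falling cline is
    # fitted on the mirrored axis and mapped back, so reversing the
    # transect direction maps c -> -c with w and the tail sides preserved
    # relative to the low-trait end
    if np.corrcoef(x, yv)[0, 1] < 0:
        swap = {"left": "right", "right": "left"}
        f = fit_geographic_cline(
            -x, yv, tail_config=swap.get(tail_config, tail_config),
            burn=burn, keep=keep, seed=seed,
        )
        m = f.model
        f.model = GeographicClineModel(
            m.pmin, m.pmax, -m.c, m.w, tail_config,
            delta_l=m.delta_r, tau_l=m.tau_r,
            delta_r=m.delta_l, tau_r=m.tau_l,
            ascending=False,
        )
        return f
    rng = np.random.default_rng(seed)

    mid = (yv.min() + yv.max()) / 2.0
    below = x[yv < mid]
    above = x[yv >= mid]
    if len(below) == 0 or len(above) == 0:
        raise ValueError("samples do not span both sides of the putative centre")
    c0 = (below.mean() + above.mean()) / 2.0
    span = max(np.ptp(x), 1e-6)
    n_par = _n_free_params(tail_config)

    theta0 = np.zeros(n_par)
    theta0[0] = float(np.quantile(yv, 0.05))
    theta0[1] = math.log(max(np.ptp(yv) * 0.9, 1e-3))
    theta0[2] = c0
    theta0[3] = math.log(span / 4.0)
    theta0[4] = math.log(max(yv.std() / 3.0, 1e-3))
    if n_par > 5:
        theta0[5] = math.log(span / 8.0)
        theta0[6] = 0.0
    if n_par > 7:
        theta0[7] = math.log(span / 8.0)
        theta0[8] = 0.0

    # broad priors on the transformed scale keep the posterior proper
    prior_mean = theta0.copy()
    prior_sd = np.full(n_par, 3.0)
    prior_sd[2] = 2.0 * span

    n = len(x)

    def loglik(theta) -> float:
        model = _unpack(theta, tail_config)
        sigma = math.exp(theta[4])
        resid = yv - cline_value(x, model)
        return -0.5 * np.sum(resid**2) / sigma**2 - n * math.log(sigma) - 0.5 * n * math.log(2 * math.pi)

    def logpost(theta) -> float:
        return loglik(theta) - 0.5 * np.sum(((theta - prior_mean) / prior_sd) ** 2)

    theta = theta0.copy()
    lp = logpost(theta)
    ll = loglik(theta)
    steps = np.full(n_par, 0.1)
    steps[2] = span / 20.0
    acc = np.zeros(n_par)
    best_ll = ll
    best_theta = theta.copy()
    w_track: list[float] = []
    ll_track: list[float] = []
    draws = {"c": [], "w": [], "logL": []}
    for it in range(burn + keep):
        # single-coordinate updates: robust for the mixed-scale parameter vector
        j = it % n_par
        prop = theta.copy()
        prop[j] += steps[j] * rng.standard_normal()
        lp_prop = logpost(prop)
        if math.log(rng.random()) < lp_prop - lp:
            theta = prop
            lp = lp_prop
            ll = loglik(theta)
            if it < burn:
                acc[j] += 1
            if ll > best_ll:
                best_ll = ll
                best_theta = theta.copy()
        if it < burn:
            if (it + 1) % (_mcmc.ADAPT_EVERY * n_par) == 0:
                _mcmc.adapt_steps(steps, acc, _mcmc.ADAPT_EVERY)
                acc[:] = 0
        else:
            w_track.append(math.exp(theta[3]))
            ll_track.append(ll)
            draws["c"].append(theta[2])
            draws["w"].append(math.exp(theta[3]))
            draws["logL"].append(ll)

    model = _unpack(best_theta, tail_config)
    k = n_par
    aicc = -2.0 * best_ll + 2 * k + (2 * k * (k + 1)) / max(n - k - 1, 1)
    w_arr = np.array(w_track)
    ll_arr = np.array(ll_track)
    support = w_arr[ll_arr >= best_ll - 2.0]
    w_hat = model.w
    if support.size:
        w_int = (float(min(support.min(), w_hat)), float(max(support.max(), w_hat)))
    else:
        w_int = (w_hat, w_hat)
    return GeographicClineFit(
        model=model,
        log_l=float(best_ll),
        aicc=float(aicc),
        width_interval=w_int,
        sigma=float(math.exp(best_theta[4])),
        n_params=k,
        draws={k_: np.array(v) for k_, v in draws.items()},
    )


def fit_all_models(
    x, proxy, configs=TAIL_CONFIGS, seed: int | None = None, **kwargs
) -> dict[str, GeographicClineFit]:
    """Fit every requested tail configuration (seeds offset per model)."""
    out = {}
    for i, cfg in enumerate(configs):
        s = None if seed is None else seed + i
        out[cfg] = fit_geographic_cline(x, proxy, tail_config=cfg, seed=s, **kwargs)
    return out


def select_model(fits: dict[str, GeographicClineFit]) -> tuple[str, GeographicClineFit]:
    """Lowest AICc wins; exact ties break toward fewer parameters."""
    if not fits:
        raise ValueError("no fitted models")
    items = sorted(
        fits.items(), key=lambda kv: (kv[1].aicc, kv[1].n_params, kv[0])
    )
    return items[0]
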