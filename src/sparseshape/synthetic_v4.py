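"""Ground-truth synthetic V4 neurons for download-free testing.

A synthetic neuron is a K-sparse signed weight vector over the 72
curvature parts; its responses are linear in the part vectors plus
additive Gaussian noise, matching the generative assumption behind the
sparse-coding model (responses are left unrectified by default so the
generator stays matched to the linear read-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig

__all__ = ["SyntheticNeuron", "make_neuron", "make_population",
           "simulate_responses", "sigma_for_snr", "convex_indices"]


def convex_indices(config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Part-vector indices that pool convex (positive-sign) maps.

    Maps alternate pos/neg per scale (channel 2s is convex), each pooled
    over the 9 grid cells.
    """
    g = config.grid_side**2
    idx = []
    for k in range(config.n_maps):
        if k % 2 == 0:
            idx.extend(range(k * g, (k + 1) * g))
    return np.array(idx)


@dataclass
class SyntheticNeuron:
    true_gamma: np.ndarray
    noise_sigma: float
    convex_bias: float
    seed: int
    neuron_id: str = ""

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(self.true_gamma)[0]


def make_neuron(K: int, convex_bias: float = 0.5, sign_mix: float = 0.5,
                noise_sigma: float = 0.0, seed: int = 0,
                config: RunConfig = DEFAULT_CONFIG) -> SyntheticNeuron:
    """K-sparse signed weights; support drawn with convex-map probability
    ``convex_bias``, each weight positive with probability ``sign_mix``,
    magnitudes uniform in [0.3, 1] (the floor keeps true effects well above
    solver tolerance)."""
    p = config.part_vector_len
    if not 1 <= K <= p:
        raise ValueError(f"K must be in [1, {p}]")
    if not (0 <= convex_bias <= 1 and 0 <= sign_mix <= 1):
        raise ValueError("convex_bias and sign_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    conv = convex_indices(config)
    conc = np.setdiff1d(np.arange(p), conv)
    weights = np.full(p, 0.0)
    probs = np.full(p, 0.0)
    probs[conv] = convex_bias / len(conv)
    probs[conc] = (1 - convex_bias) / len(conc)
    if probs.sum() == 0:
        raise ValueError("degenerate convex_bias")
    support = rng.choice(p, size=K, replace=False, p=probs / probs.sum())
    mags = rng.uniform(0.3, 1.0, size=K)
    signs = np.where(rng.random(K) < sign_mix, 1.0, -1.0)
    weights[support] = mags * signs
    return SyntheticNeuron(true_gamma=weights, noise_sigma=noise_sigma,
                           convex_bias=convex_bias, seed=seed)


def make_population(n: int, K: int, convex_bias: float = 0.5,
                    sign_mix: float = 0.5, noise_sigma: float = 0.0,
                    seed: int = 0, config: RunConfig = DEFAULT_CONFIG
                    ) -> list[SyntheticNeuron]:
    """Population with independent per-neuron streams branched from one
    global seed, so any sub-population is reproducible piecewise."""
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n)):
        sub = int(child.generate_state(1)[0] % (2**31))
        nrn = make_neuron(K, convex_bias, sign_mix, noise_sigma, seed=sub,
                          config=config)
        nrn.neuron_id = f"syn-{i:03d}"
        out.append(nrn)
    return out


def sigma_for_snr(D: np.ndarray, gamma: np.ndarray, snr: float) -> float:
    """Noise std giving var(signal)/var(noise) = snr for these stimuli."""
    signal = D @ gamma
    return float(np.std(signal) / np.sqrt(snr))


def simulate_responses(neuron: SyntheticNeuron, D: np.ndarray,
                       stimulus_ids=None, seed: int | None = None,
                       rectify_responses: bool = False) -> pd.DataFrame:
    """R_t = D_t^T gamma_true + eps_t, eps ~ N(0, sigma^2), seeded.

    Negative totals are floored at zero only when ``rectify_responses``
    is set (default off: the generative model matches the unrectified
    linear read-out).
    """
    D = np.asarray(D, dtype=float)
    r = D @ neuron.true_gamma
    rng = np.random.default_rng(neuron.seed if seed is None else seed)
    if neuron.noise_sigma > 0:
        r = r + rng.normal(0.0, neuron.noise_sigma, size=len(r))
    if rectify_responses:
        r = np.maximum(r, 0.0)
    ids = stimulus_ids if stimulus_ids is not None else np.arange(len(r))
    return pd.DataFrame({"neuron_id": neuron.neuron_id or "syn-000",
                         "stimulus_id": ids, "response": r})


def save_ground_truth(neuron: SyntheticNeuron, path) -> None:
    with open(path, "w") as fh:
        json.dump({"neuron_id": neuron.neuron_id,
                   "true_gamma": neuron.true_gamma.tolist(),
                   "noise_sigma": neuron.noise_sigma,
                   "convex_bias": neuron.convex_bias,
                   "seed": neuron.seed}, fh)
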