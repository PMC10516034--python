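"""Spike-rate-matched surrogate rasters and chance-level references.

A surrogate raster keeps the source raster's shape and spike count but
scatters the spikes uniformly at random over all channel x time-bin cells
(sampling positions without replacement, so the raster stays binary).  This
abolishes any spatiotemporal structure while matching the spike rate, making
an ensemble of surrogates the empirical chance-level reference for both the
motif-class spectrum (the per-class mean mu) and the 4D entropy.

The normalized prevalence ``M/mu - 1`` compares the observed class
prevalence M with its chance expectation: values above 0 indicate network
structure beyond what the spike rate alone produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import LagTensor, LagWindow, compute_triple_correlation
from .entropy import EntropyValue, estimate_pdf, shannon_entropy
from .errors import InputError
from .motifs import CLASS_LABELS, MotifSpectrum, motif_spectrum
from .raster import SpikeRaster

__all__ = [
    "SurrogateEnsemble",
    "generate_surrogate",
    "surrogate_ensemble",
    "normalized_prevalence",
]


def generate_surrogate(raster: SpikeRaster, rng: np.random.Generator) -> SpikeRaster:
    """One spike-rate-matched surrogate: all spikes shuffled over time and space.

    Spike positions are a uniform sample without replacement of all
    ``n_channels * n_bins`` cells, so the surrogate is binary and has
    exactly the source's spike count.
    """
    n_cells = raster.n_channels * raster.n_bins
    k = raster.spike_count
    if k > n_cells:
        raise InputError(f"cannot place {k} spikes in {n_cells} cells")
    flat = np.zeros(n_cells, dtype=np.uint8)
    if k:
        flat[rng.choice(n_cells, size=k, replace=False)] = 1
    return SpikeRaster(
        flat.reshape(raster.n_channels, raster.n_bins),
        bin_width=raster.bin_width,
        channel_ids=raster.channel_ids,
        t0=raster.t0,
    )


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Results of the full analysis chain on ``n_iterations`` surrogates.

    Stores per-iteration spectra and entropies plus the mean lag tensor and
    the per-class mean mu used as the chance-level expectation.
    """

    window: LagWindow
    n_iterations: int
    seed: int | None
    spectra: tuple[MotifSpectrum, ...]
    entropies: tuple[EntropyValue, ...]
    mean_tensor: np.ndarray
    spike_count: int
    mu: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        M = np.stack([s.M for s in self.spectra]).astype(float)
        object.__setattr__(self, "mu", M.mean(axis=0))

    @property
    def entropy_values(self) -> np.ndarray:
        return np.array([e.H for e in self.entropies])

    def entropy_summary(self) -> dict[str, float]:
        H = self.entropy_values
        return {
            "mean": float(H.mean()),
            "min": float(H.min()),
            "q25": float(np.percentile(H, 25)),
            "median": float(np.percentile(H, 50)),
            "q75": float(np.percentile(H, 75)),
            "max": float(H.max()),
        }

    def mu_summary(self) -> dict[str, dict[str, float]]:
        """Per-class mean and quartiles of the surrogate prevalences."""
        M = np.stack([s.M for s in self.spectra]).astype(float)
        out = {}
        for i, lab in enumerate(CLASS_LABELS):
            col = M[:, i]
            out[lab] = {
                "mu": float(col.mean()),
                "min": float(col.min()),
                "q25": float(np.percentile(col, 25)),
                "median": float(np.percentile(col, 50)),
                "q75": float(np.percentile(col, 75)),
                "max": float(col.max()),
            }
        return out


def surrogate_ensemble(
    raster: SpikeRaster,
    window: LagWindow,
    n: int = 100,
    seed: int | None = None,
) -> SurrogateEnsemble:
    """Run the tensor→spectrum→PDF→entropy chain on ``n`` seeded surrogates."""
    if n < 1:
        raise InputError("ensemble needs n >= 1 iterations")
    rng = np.random.default_rng(seed)
    spectra: list[MotifSpectrum] = []
    entropies: list[EntropyValue] = []
    mean_tensor = np.zeros(window.shape, dtype=float)
    for _ in range(n):
        surr = generate_surrogate(raster, rng)
        tensor = compute_triple_correlation(surr, window)
        mean_tensor += tensor.values
        spectra.append(motif_spectrum(tensor))
        entropies.append(shannon_entropy(estimate_pdf(tensor)))
    mean_tensor /= n
    return SurrogateEnsemble(
        window=window,
        n_iterations=n,
        seed=seed,
        spectra=tuple(spectra),
        entropies=tuple(entropies),
        mean_tensor=mean_tensor,
        spike_count=raster.spike_count,
    )


def normalized_prevalence(
    spectrum: MotifSpectrum,
    ensemble: SurrogateEnsemble | None = None,
    mu: np.ndarray | None = None,
) -> np.ndarray:
    """Per-class normalized prevalence ``M/mu - 1``.

    ``mu`` defaults to the ensemble's per-class surrogate mean; passing an
    explicit ``mu`` array (e.g. an analytic conditioned expectation) is the
    hook for other chance models.  Classes with ``mu == 0`` return NaN (an
    undefined marker), never infinity.
    """
    if mu is None:
        if ensemble is None:
            raise InputError("provide either a surrogate ensemble or an explicit mu")
        if ensemble.window != spectrum.window:
            raise InputError(
                f"spectrum window {spectrum.window} != ensemble window {ensemble.window}"
            )
        mu = ensemble.mu
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (14,):
        raise InputError(f"mu must have 14 entries, got shape {mu.shape}")
    M = spectrum.M.astype(float)
    out = np.full(14, np.nan)
    ok = mu != 0
    out[ok] = M[ok] / mu[ok] - 1.0
    return out
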