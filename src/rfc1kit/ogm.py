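"""Allele sizing from optical-mapping intermarker distances.

Labelled-molecule distances across the repeat locus form one or two Gaussian
clouds (one per allele); the expansion size of each allele follows from the
component mean: ``size = (mean - reference) / motif_len`` repeat units, with
the non-expanded reference distance defaulting to 6858 bp.

The mixture is fitted by expectation-maximization with a variance shared
between components (measurement noise does not depend on the allele),
initialized at the 25th/75th percentiles; one- and two-component fits are
compared by BIC, so a homozygous sample is reported as a single component
(both alleles get the same size).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

REFERENCE_INTERMARKER_BP = 6858.0
_SD_FLOOR = 1.0


@dataclass
class MixtureResults:
    """Fitted Gaussian mixture over intermarker distances."""

    k: int
    means: np.ndarray                # ascending, bp
    sd: float                        # shared component SD, bp
    weights: np.ndarray
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    n_obs: int
    loglik_path: np.ndarray          # per-iteration log-likelihood (k final)
    reference: float = REFERENCE_INTERMARKER_BP
    motif_len: int = 5

    @property
    def sds(self) -> np.ndarray:
        return np.full(self.k, self.sd)

    @property
    def allele_sizes(self) -> tuple[int, int]:
        return distances_to_repeat_sizes(self, self.reference, self.motif_len)

    def summary(self) -> str:
        lines = [
            f"Gaussian mixture allele sizing (n={self.n_obs} molecules)",
            f"components: {self.k}   converged: {self.converged} "
            f"({self.n_iter} iterations)   BIC: {self.bic:.1f}",
        ]
        sizes = self.allele_sizes
        for i in range(self.k):
            lines.append(f"  component {i + 1}: mean {self.means[i]:.1f} bp, "
                         f"sd {self.sd:.1f} bp, weight {self.weights[i]:.2f}")
        lines.append(f"allele sizes: {sizes[0]} / {sizes[1]} repeat units "
                     f"(reference {self.reference:.0f} bp, "
                     f"motif {self.motif_len} bp)")
        return "\n".join(lines)


class RepeatSizeMixture:
    """Model: intermarker distances ~ mixture of <= 2 shared-variance
    Gaussians; ``fit()`` returns :class:`MixtureResults`."""

    def __init__(self, distances, reference: float = REFERENCE_INTERMARKER_BP,
                 motif_len: int = 5):
        self.distances = np.asarray(distances, dtype=float).ravel()
        if self.distances.size < 4:
            raise ValueError("need at least 4 observations")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")
        self.reference = float(reference)
        self.motif_len = int(motif_len)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "RepeatSizeMixture":
        return cls(np.loadtxt(path, ndmin=1), **kwargs)

    # -- EM internals ------------------------------------------------------
    def _fit_k1(self) -> MixtureResults:
        x = self.distances
        mu = float(x.mean())
        sd = max(float(x.std()), _SD_FLOOR)
        ll = float(stats.norm.logpdf(x, mu, sd).sum())
        bic = 2 * np.log(x.size) - 2 * ll
        return MixtureResults(1, np.array([mu]), sd, np.array([1.0]), ll, bic,
                              0, True, x.size, np.array([ll]),
                              self.reference, self.motif_len)

    def _fit_k2(self, tol: float, max_iter: int) -> MixtureResults:
        x = self.distances
        n = x.size
        mu = np.percentile(x, [25.0, 75.0]).astype(float)
        if mu[0] == mu[1]:
            mu[1] += _SD_FLOOR
        sd = max(float(x.std()), _SD_FLOOR)
        w = np.array([0.5, 0.5])
        path = []
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step
            logp = (np.log(w)[None, :]
                    + stats.norm.logpdf(x[:, None], mu[None, :], sd))
            norm = np.logaddexp(logp[:, 0], logp[:, 1])
            ll = float(norm.sum())
            path.append(ll)
            r = np.exp(logp - norm[:, None])
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                converged = True
                break
            prev_ll = ll
            # M-step (shared variance)
            nk = r.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            w = nk / n
            mu = (r * x[:, None]).sum(axis=0) / nk
            var = float((r * (x[:, None] - mu[None, :]) ** 2).sum() / n)
            sd = max(np.sqrt(var), _SD_FLOOR)
        order = np.argsort(mu)
        ll = path[-1]
        bic = 4 * np.log(n) - 2 * ll
        return MixtureResults(2, mu[order], sd, np.asarray(w)[order], ll, bic,
                              it, converged, n, np.array(path),
                              self.reference, self.motif_len)

    def fit(self, k_max: int = 2, tol: float = 1e-6,
            max_iter: int = 500) -> MixtureResults:
        """Fit k=1 and (if ``k_max`` >= 2) k=2 and select by BIC."""
        x = self.distances
        if np.ptp(x) == 0:
            return self._fit_k1()         # degenerate: identical values
        fit1 = self._fit_k1()
        if k_max < 2:
            return fit1
        fit2 = self._fit_k2(tol, max_iter)
        return fit2 if fit2.bic < fit1.bic else fit1


def fit_gaussian_mixture(distances, k_max: int = 2, tol: float = 1e-6,
                         max_iter: int = 500,
                         reference: float = REFERENCE_INTERMARKER_BP,
                         motif_len: int = 5) -> MixtureResults:
    """Functional wrapper around :class:`RepeatSizeMixture`."""
    return RepeatSizeMixture(distances, reference, motif_len).fit(
        k_max=k_max, tol=tol, max_iter=max_iter)


def distances_to_repeat_sizes(fit: MixtureResults,
                              reference: float = REFERENCE_INTERMARKER_BP,
                              motif_len: int = 5) -> tuple[int, int]:
    """Convert component means to allele sizes in repeat units.

    ``size = round((mean - reference) / motif_len)``, floored at 0; a
    one-component fit assigns the same size to both alleles.  A mean more
    than 3 SD below the reference triggers a negative-expansion warning.
    """
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    sizes = []
    for mean in fit.means:
        if mean < reference - 3 * fit.sd:
            warnings.warn(f"component mean {mean:.0f} bp is below the "
                          f"non-expanded reference {reference:.0f} bp",
                          stacklevel=2)
        sizes.append(max(0, int(round((mean - reference) / motif_len))))
    if len(sizes) == 1:
        sizes = [sizes[0], sizes[0]]
    return tuple(sorted(sizes))
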