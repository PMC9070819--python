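"""Principal-waveform reconstruction of GRF and joint-angle curves.

For one height and one variable, the 100-point phase curves of all trials are
arranged as a ``n x p`` matrix (``n`` = 100 phase points as observations,
``p`` = trials as variables), column-standardized, and eigen-decomposed via
the covariance matrix.  The cumulative contribution of the leading ``m``
eigenvalues, G(m) = sum_{i<=m} lambda_i / sum_k lambda_k, selects how many
components to retain (the dominant shared waveform usually makes G(1) > 0.9);
the retained scores times the transposed coefficient matrix, de-standardized
(times the column sd, plus the column mean), give the *principal waveform*.
The curve actually reported is the column-wise mean of the de-standardized
reconstruction, and its value at the final phase point (maximum elbow
flexion) is the endpoint handed off to downstream structural analysis.

Conventions the decomposition fixes for reproducibility: sample standard
deviation (divisor n-1) for standardization, eigenvector sign such that the
largest-magnitude loading is positive, and eigenvalues clipped at zero
(covariance matrices are positive semi-definite; tiny negative round-off is
noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, SignalError


@dataclass
class PCAResult:
    """Standardization parameters, sorted eigenpairs, scores and G(m)."""

    mean: np.ndarray          # (p,) column means
    sd: np.ndarray            # (p,) column sample standard deviations
    eigenvalues: np.ndarray   # (p,) non-increasing, >= 0
    eigenvectors: np.ndarray  # (p, p) orthonormal columns, sign-fixed
    scores: np.ndarray        # (n, p) standardized data projected on eigenvectors
    contribution: np.ndarray  # (p,) cumulative contribution G(m), G(p) = 1

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class PrincipalWaveform:
    """De-standardized reconstruction from the retained components."""

    matrix: np.ndarray         # (n, p) reconstructed trials
    representative: np.ndarray  # (n,) collapse across trials (mean by default)
    endpoint: float            # representative value at the final phase point
    n_retained: int


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring; returns (Z, mean, sd) with sd the sample
    (n-1 divisor) standard deviation.  A zero-variance column is an error
    naming the column rather than a silent drop."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("standardize expects a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise SignalError("standardize: matrix contains non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise SignalError(f"zero-variance column(s) {zero.tolist()} cannot be standardized")
    return (X - mean) / sd, mean, sd


def decompose(X: np.ndarray) -> PCAResult:
    """Standardize and eigen-decompose the covariance matrix of ``X``.

    Scores are the standardized data projected onto the eigenvectors;
    ``contribution[m-1]`` is G(m).
    """
    Z, mean, sd = standardize(X)
    n = Z.shape[0]
    cov = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: the largest-magnitude loading of each vector is positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    total = evals.sum()
    if total <= 0:
        raise SignalError("covariance matrix has zero total variance")
    contribution = np.cumsum(evals) / total
    contribution[-1] = 1.0  # exact by definition; guards cumulative round-off
    scores = Z @ evecs
    return PCAResult(mean=mean, sd=sd, eigenvalues=evals, eigenvectors=evecs,
                     scores=scores, contribution=contribution)


def select_components(result: PCAResult, threshold: float = 0.90) -> tuple[int, bool]:
    """Smallest m with G(m) >= threshold, plus a flag for the m == 1 case
    (a single dominant waveform)."""
    m = int(np.searchsorted(result.contribution, threshold) + 1)
    m = min(m, result.n_components)
    return m, m == 1


def reconstruct(result: PCAResult, m: int, collapse: str = "mean") -> PrincipalWaveform:
    """Reconstruct from the first ``m`` components and de-standardize.

    ``collapse`` ("mean" or "median") controls how the per-trial columns are
    collapsed into the single representative curve; the endpoint is that
    curve's value at the final (100th) phase point.
    """
    if not 1 <= m <= result.n_components:
        raise ConfigurationError(f"m={m} outside [1, {result.n_components}]")
    Zhat = result.scores[:, :m] @ result.eigenvectors[:, :m].T
    Xhat = Zhat * result.sd + result.mean
    if collapse == "mean":
        rep = Xhat.mean(axis=1)
    elif collapse == "median":
        rep = np.median(Xhat, axis=1)
    else:
        raise ConfigurationError("collapse must be 'mean' or 'median'")
    return PrincipalWaveform(matrix=Xhat, representative=rep,
                             endpoint=float(rep[-1]), n_retained=m)


def extract_endpoint(waveform: PrincipalWaveform) -> float:
    """Representative value at the final phase point (maximum elbow flexion)."""
    return float(waveform.representative[-1])


def principal_waveform(X: np.ndarray, threshold: float = 0.90,
                       collapse: str = "mean") -> tuple[PrincipalWaveform, PCAResult, int]:
    """Decompose, select by G(m) >= threshold, reconstruct: the full per-variable
    pipeline in one call."""
    result = decompose(X)
    m, _ = select_components(result, threshold)
    return reconstruct(result, m, collapse), result, m
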