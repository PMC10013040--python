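"""Linear inverse modeling: minimum norm with sLORETA standardization.

Given a lead field L (sensors x sources) the minimum-norm inverse with
identity noise covariance is

    M = L^T (L L^T + lambda I)^(-1)

and sLORETA standardization divides each source's estimate by the square
root of the corresponding diagonal entry of the resolution matrix
R = M L. The standardized operator is computed once per head model - it
depends only on electrode placement, never on the measured voltages - and
is then applied to as many EEG snapshots as needed. For noiseless
single-source activity the standardized estimate attains its maximum
magnitude at the true source (sLORETA's zero-localization-error property),
which the test suite verifies by brute force.

Current source density (CSD) values downstream use the magnitude of the
standardized estimate, so region/time aggregates are non-negative; the
signed estimate is available via ``magnitude=False``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np


@dataclass
class InverseKernel:
    """Precomputed sources-by-sensors linear inverse operator."""

    kernel: np.ndarray
    regularization_lambda: float
    average_reference: bool = True
    leadfield_id: str = ""

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("inverse kernel contains non-finite entries")

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.kernel.shape[1]


@dataclass
class SourceCsd:
    """Per-source current density estimates over a time window."""

    values: np.ndarray   # (n_sources, n_times)
    times: np.ndarray    # s, relative to the event trough
    magnitude: bool = True

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.values.shape[1] != self.times.size:
            raise ValueError("values and times disagree on the number of timepoints")


def _average_reference_projector(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def auto_lambda(L: np.ndarray, snr: float = 3.0) -> float:
    """Default Tikhonov weight: trace(L L^T) / (n_sensors * SNR^2).

    A standard heuristic scaling the regularizer to the mean sensor-space
    signal power at an assumed amplitude SNR (default 3).
    """
    n = L.shape[0]
    return float(np.trace(L @ L.T) / (n * snr**2))


def compute_inverse_kernel(
    head,
    lambda_: float | str = "auto",
    average_reference: bool = True,
    sloreta: bool = True,
    snr: float = 3.0,
) -> InverseKernel:
    """Minimum-norm (optionally sLORETA-standardized) inverse kernel.

    Parameters
    ----------
    head : ToyHeadModel
        Must expose a full-sensor-rank ``leadfield`` (sensors x sources).
    lambda_ : float or "auto"
        Tikhonov regularization weight; "auto" uses :func:`auto_lambda`.
    average_reference : bool
        Project the lead field (and, in :func:`apply_kernel`, the data)
        to the average reference before inversion. Minimum-norm solvers
        conventionally operate in average reference; disable for analytic
        checks on synthetic operators.
    sloreta : bool
        Divide each source row by sqrt(diag(M L)).
    """
    L = np.asarray(head.leadfield, dtype=float)
    if average_reference:
        L = _average_reference_projector(L.shape[0]) @ L
    lam = auto_lambda(L, snr) if lambda_ == "auto" else float(lambda_)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    G = L @ L.T + lam * np.eye(L.shape[0])
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"(L L^T + lambda I) is singular at lambda={lam:g}; "
            "increase the regularization weight"
        ) from exc
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e14:
        raise ValueError(
            f"(L L^T + lambda I) is numerically singular (cond={cond:.2e}) "
            f"at lambda={lam:g}; increase the regularization weight"
        )
    M = L.T @ Ginv
    if sloreta:
        diag = np.einsum("ij,ji->i", M, L)  # diag of the resolution matrix
        if np.any(diag <= 0):
            raise ValueError("non-positive resolution diagonal; increase lambda")
        M = M / np.sqrt(diag)[:, None]
    lf_id = hashlib.sha1(np.ascontiguousarray(head.leadfield).tobytes()).hexdigest()[:12]
    return InverseKernel(
        kernel=M,
        regularization_lambda=lam,
        average_reference=average_reference,
        leadfield_id=lf_id,
    )


def apply_kernel(
    kernel: InverseKernel,
    snapshots: np.ndarray,
    times: np.ndarray | None = None,
    magnitude: bool = True,
) -> SourceCsd:
    """Apply the inverse kernel to EEG snapshots (sensors x timepoints).

    Returns per-source estimates; with ``magnitude`` (the default) the
    absolute value is taken per source per timepoint, giving non-negative
    CSD values.
    """
    V = np.atleast_2d(np.asarray(snapshots, dtype=float))
    if V.shape[0] != kernel.n_sensors:
        if V.shape[1] == kernel.n_sensors and V.shape[0] != kernel.n_sensors:
            raise ValueError(
                f"snapshots must be sensors x timepoints with "
                f"{kernel.n_sensors} sensors; got shape {V.shape}"
            )
        raise ValueError(
            f"snapshot sensor count {V.shape[0]} does not match kernel "
            f"({kernel.n_sensors})"
        )
    if kernel.average_reference:
        V = V - V.mean(axis=0, keepdims=True)
    S = kernel.kernel @ V
    if magnitude:
        S = np.abs(S)
    if times is None:
        times = np.arange(V.shape[1], dtype=float)
    return SourceCsd(values=S, times=times, magnitude=magnitude)


@dataclass
class DipoleGridConfig:
    """Bookkeeping for a fixed source grid: one scalar dipole per voxel.

    Defaults describe the standard anatomical-template grid used for
    mixed cortical/sub-cortical modeling: 15,002 cortical vertices plus
    5,095 sub-cortical vertices for 20,097 dipoles in total.
    """

    n_cortical_vertices: int = 15002
    n_subcortical_vertices: int = 5095
    n_dipoles: int = field(default=None)
    dipoles_per_voxel: int = 1

    def __post_init__(self):
        if self.n_dipoles is None:
            self.n_dipoles = self.n_cortical_vertices + self.n_subcortical_vertices
        self.validate()

    def validate(self) -> int:
        """Check the grid arithmetic; returns the total dipole count."""
        if min(self.n_cortical_vertices, self.n_subcortical_vertices) < 0:
            raise ValueError("vertex counts must be non-negative")
        if self.dipoles_per_voxel != 1:
            raise ValueError("grid assumes a single dipole per voxel")
        expected = self.n_cortical_vertices + self.n_subcortical_vertices
        if self.n_dipoles != expected:
            raise ValueError(
                f"dipole count {self.n_dipoles} inconsistent with "
                f"{self.n_cortical_vertices} cortical + "
                f"{self.n_subcortical_vertices} sub-cortical vertices "
                f"(= {expected})"
            )
        return self.n_dipoles
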