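"""Environmentally extended multi-regional input–output (EE-MRIO) accounting.

Given an interindustry flow table ``Z``, final demand ``Y`` and gross output
``x`` for ``R`` regions × ``S`` sectors, together with production-based (PBA)
sectoral mercury emissions, this module computes the region-by-region matrix
of emissions embodied in final consumption:

    ``flows[r, s] = e_r · L · y_s``

where ``e_r`` is the emission-coefficient (intensity) vector zeroed outside
region ``r``, ``L = (I − A)⁻¹`` is the Leontief inverse of the technical
coefficient matrix ``A = Z · diag(x)⁻¹``, and ``y_s`` is region ``s``'s final
demand column.  Row sums of ``flows`` recover PBA country totals; column sums
are consumption-based (CBA) totals; off-diagonal entries are emissions
embodied in international trade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import NumericalError, ValidationError

_BALANCE_RTOL = 1e-8


def _block_index(regions, sectors) -> pd.MultiIndex:
    return pd.MultiIndex.from_product([regions, sectors], names=["region", "sector"])


@dataclass
class MRIOTable:
    """A multiregional input–output economy in region-major block order.

    ``Z`` is (R·S)×(R·S) interindustry flows, ``Y`` is (R·S)×R final demand
    by destination region, ``x`` is gross output, all in one currency unit
    per year.  The accounting identity ``x = Z·1 + Y·1`` must hold row-wise.
    """

    regions: list[str]
    sectors: list[str]
    Z: np.ndarray
    Y: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        n = self.n_flows
        if self.Z.shape != (n, n):
            raise ValidationError(f"Z must be {n}×{n}, got {self.Z.shape}")
        if self.Y.shape != (n, self.n_regions):
            raise ValidationError(f"Y must be {n}×{self.n_regions}, got {self.Y.shape}")
        if self.x.shape != (n,):
            raise ValidationError(f"x must have length {n}, got {self.x.shape}")
        if np.any(self.Z < 0) or np.any(self.Y < 0) or np.any(self.x < 0):
            raise ValidationError("Z, Y and x must be nonnegative")
        supply = self.Z.sum(axis=1) + self.Y.sum(axis=1)
        scale = np.maximum(np.abs(self.x), 1.0)
        if np.any(np.abs(supply - self.x) > _BALANCE_RTOL * scale):
            raise ValidationError("accounting identity x = Z·1 + Y·1 violated")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def n_flows(self) -> int:
        return self.n_regions * self.n_sectors

    def region_slice(self, r: int) -> slice:
        s = self.n_sectors
        return slice(r * s, (r + 1) * s)

    def index(self) -> pd.MultiIndex:
        return _block_index(self.regions, self.sectors)

    # ---- CSV round trip (headers are "region:sector") -------------------
    def to_csv_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        labels = [f"{r}:{s}" for r, s in self.index()]
        pd.DataFrame(self.Z, index=labels, columns=labels).to_csv(path / "Z.csv")
        pd.DataFrame(self.Y, index=labels, columns=self.regions).to_csv(path / "Y.csv")
        pd.Series(self.x, index=labels, name="x").to_csv(path / "x.csv")

    @classmethod
    def from_csv_dir(cls, path) -> "MRIOTable":
        path = Path(path)
        z = pd.read_csv(path / "Z.csv", index_col=0)
        y = pd.read_csv(path / "Y.csv", index_col=0)
        x = pd.read_csv(path / "x.csv", index_col=0)["x"]
        pairs = [lbl.split(":", 1) for lbl in z.index]
        regions = list(dict.fromkeys(p[0] for p in pairs))
        sectors = list(dict.fromkeys(p[1] for p in pairs))
        return cls(regions, sectors, z.values, y.values, x.values)


@dataclass
class EmissionAccount:
    """Production-based sectoral emissions and derived intensities.

    ``pba`` is Mg/yr per (region, sector) in the table's block order;
    ``intensity`` (Mg per currency unit) is ``pba / x`` where output is
    positive and zero elsewhere.
    """

    regions: list[str]
    sectors: list[str]
    pba: np.ndarray
    intensity: np.ndarray

    @classmethod
    def from_pba(cls, table: MRIOTable, pba: np.ndarray) -> "EmissionAccount":
        pba = np.asarray(pba, dtype=float).reshape(-1)
        if pba.shape != (table.n_flows,):
            raise ValidationError("pba length does not match the economy")
        if np.any(pba < 0):
            raise ValidationError("pba must be nonnegative")
        intensity = np.divide(pba, table.x, out=np.zeros_like(pba), where=table.x > 0)
        return cls(list(table.regions), list(table.sectors), pba, intensity)

    def country_totals(self) -> pd.Series:
        idx = _block_index(self.regions, self.sectors)
        return pd.Series(self.pba, index=idx).groupby(level="region", sort=False).sum()

    def total(self) -> float:
        return float(self.pba.sum())


def aggregate_sources(
    source_emissions: pd.DataFrame, source_to_sector: dict[str, str], table: MRIOTable
) -> np.ndarray:
    """Map per-(region, source-category) emissions onto MRIO sectors.

    ``source_emissions`` has columns ``region``, ``source``, ``emissions``;
    ``source_to_sector`` is a many-to-one mapping from inventory source
    categories to sector labels of ``table``.  Returns a PBA vector in the
    table's block order.  Every source present in the data must be mapped.
    """
    pba = np.zeros(table.n_flows)
    pos = {(r, s): i for i, (r, s) in enumerate(table.index())}
    for _, row in source_emissions.iterrows():
        src = row["source"]
        if src not in source_to_sector:
            raise ValidationError(f"unmapped emission source {src!r}")
        key = (row["region"], source_to_sector[src])
        if key not in pos:
            raise ValidationError(f"unknown region/sector pair {key!r}")
        pba[pos[key]] += float(row["emissions"])
    return pba


def technical_coefficients(table: MRIOTable) -> np.ndarray:
    """Input requirements per unit output: ``A_ij = Z_ij / x_j``.

    Columns with zero gross output must carry no interindustry flows.
    """
    zero = table.x == 0
    if np.any(zero & (table.Z.sum(axis=0) > 0)):
        bad = int(np.flatnonzero(zero & (table.Z.sum(axis=0) > 0))[0])
        raise ValidationError(f"sector {bad} has zero output but nonzero inputs")
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(zero[None, :], 0.0, table.Z / np.where(zero, 1.0, table.x)[None, :])
    return A


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0


def leontief_inverse(A: np.ndarray, *, rtol: float = 1e-10) -> np.ndarray:
    """``L = (I − A)⁻¹`` by LU factorisation, with a residual check.

    Raises :class:`NumericalError`, reporting the spectral radius, when the
    series does not converge (ρ(A) ≥ 1) or the factorisation is singular.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    ImA = np.eye(n) - A
    try:
        lu, piv = scipy.linalg.lu_factor(ImA)
        L = scipy.linalg.lu_solve((lu, piv), np.eye(n))
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            f"I − A is singular (spectral radius of A = {spectral_radius(A):.6f})"
        ) from exc
    residual = np.abs(ImA @ L - np.eye(n)).max()
    rho = spectral_radius(A)
    if rho >= 1 or not np.isfinite(residual) or residual > rtol * max(1.0, np.abs(L).max()):
        raise NumericalError(
            f"Leontief series does not converge: spectral radius {rho:.6f}, residual {residual:.3e}"
        )
    return L


@dataclass
class EmbodiedFlowMatrix:
    """R×R mercury emissions embodied in consumption, Mg/yr.

    Entry (r, s): emissions physically produced in region ``r`` that are
    attributable to final consumption in region ``s``.  The diagonal is the
    domestic part; row sums are PBA totals, column sums CBA totals.
    """

    regions: list[str]
    flows: np.ndarray

    def __post_init__(self) -> None:
        self.flows = np.asarray(self.flows, dtype=float)
        n = len(self.regions)
        if self.flows.shape != (n, n):
            raise ValidationError(f"flow matrix must be {n}×{n}")
        if np.any(self.flows < -1e-12 * max(1.0, np.abs(self.flows).max())):
            raise ValidationError("embodied flows must be nonnegative")
        self.flows = np.maximum(self.flows, 0.0)

    def pba_totals(self) -> pd.Series:
        return pd.Series(self.flows.sum(axis=1), index=self.regions, name="pba")

    def cba_totals(self) -> pd.Series:
        return pd.Series(self.flows.sum(axis=0), index=self.regions, name="cba")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flows, index=self.regions, columns=self.regions)


def embodied_flow_matrix(account: EmissionAccount, table: MRIOTable) -> EmbodiedFlowMatrix:
    """Full R×R embodied-emission flow matrix (diagonal included).

    Computes ``W = diag(e) · L · Y`` and aggregates rows by source region;
    conservation (Σ flows = Σ pba) holds whenever the table is balanced.
    """
    if account.regions != list(table.regions) or account.sectors != list(table.sectors):
        raise ValidationError("emission account does not match the economy's labels")
    A = technical_coefficients(table)
    L = leontief_inverse(A)
    W = (account.intensity[:, None] * L) @ table.Y  # (R·S) × R
    R, S = table.n_regions, table.n_sectors
    flows = W.reshape(R, S, R).sum(axis=1)
    # suppress LU roundoff: entries this far below the leading flows are
    # numerical noise (and would otherwise break exact autarky nulls)
    if flows.size:
        flows[np.abs(flows) < 1e-12 * np.abs(flows).max()] = 0.0
    return EmbodiedFlowMatrix(list(table.regions), flows)


def net_transfers(flows: EmbodiedFlowMatrix) -> pd.Series:
    """Per-region net embodied emissions, PBA − CBA (Mg/yr); sums to zero."""
    return (flows.pba_totals() - flows.cba_totals()).rename("net")


def top_net_flows(flows: EmbodiedFlowMatrix, k: int) -> list[tuple[str, str, float]]:
    """The ``k`` largest pairwise net flows ``max(flows_rs − flows_sr, 0)``.

    Sorted descending; exact ties break lexicographically on the
    (source, destination) labels.  Zero net pairs are never reported.
    """
    if k < 0:
        raise ValidationError("k must be nonnegative")
    F = flows.flows
    out = []
    for i, src in enumerate(flows.regions):
        for j, dst in enumerate(flows.regions):
            if i == j:
                continue
            net = F[i, j] - F[j, i]
            if net > 0:
                out.append((src, dst, float(net)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out[:k]


def embodied_trade_share(flows: EmbodiedFlowMatrix) -> float:
    """Fraction of total emissions embodied in international trade."""
    total = flows.flows.sum()
    if total == 0:
        raise ValidationError("trade share undefined for an all-zero flow matrix")
    offdiag = flows.flows[~np.eye(len(flows.regions), dtype=bool)].sum()
    return float(offdiag / total)
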