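"""Shared domain types and file formats for elastic/quasi-elastic scattering data.

Two on-disk dialects are supported:

* a UTF-8 TSV dialect for elastic scans, with ``#``-prefixed metadata header
  lines and one row per (T, P, q) point — diff-able and suitable for fixtures;
* an HDF5 store for quasi-elastic S(q, ω) maps with their resolution
  measurement, laid out as ``/qens/{q, omega, S, sigma, T, P}`` and
  ``/resolution/{q, omega, R, sigma}``.

Sign convention: positive ω means energy transferred to the sample.  All
loaders validate invariants and refuse inputs that violate them; the single
documented repair is re-normalization of resolution profiles to unit area on
load.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = "piezodyn-1"

_ELASTIC_COLUMNS = ("T", "P", "q", "intensity", "sigma")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Raised when data violate a domain-type invariant."""


@dataclass(frozen=True)
class Condition:
    """A single (temperature, pressure) measurement condition."""

    temperature: float  # K
    pressure: float  # bar
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.pressure >= 1:
            raise ValidationError(f"pressure must be >= 1 bar, got {self.pressure}")

    @property
    def key(self) -> tuple[float, float]:
        return (self.temperature, self.pressure)


@dataclass
class ElasticScanSet:
    """Elastic intensities I(q) for a set of (T, P) conditions.

    ``intensity`` and ``sigma`` have shape (n_conditions, n_q); ``mask`` is a
    per-q boolean with True marking usable channels.
    """

    q: np.ndarray
    conditions: list[Condition]
    intensity: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.mask is None:
            self.mask = np.ones(self.q.size, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValidationError("q must be a non-empty 1-D vector")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing")
        n_c, n_q = len(self.conditions), self.q.size
        if n_c == 0:
            raise ValidationError("at least one condition is required")
        if self.intensity.shape != (n_c, n_q) or self.sigma.shape != (n_c, n_q):
            raise ValidationError(
                f"intensity/sigma must have shape {(n_c, n_q)}, "
                f"got {self.intensity.shape} and {self.sigma.shape}"
            )
        if self.mask.shape != (n_q,):
            raise ValidationError("mask must be per-q")
        if np.any(self.intensity[:, self.mask] < 0):
            raise ValidationError("intensity must be >= 0 on unmasked channels")
        if np.any(self.sigma <= 0):
            raise ValidationError("sigma must be strictly positive")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def condition_index(self, temperature: float, pressure: float) -> int:
        for i, c in enumerate(self.conditions):
            if np.isclose(c.temperature, temperature) and np.isclose(c.pressure, pressure):
                return i
        raise KeyError(f"no condition at T={temperature} K, P={pressure} bar")

    def select_pressure(self, pressure: float) -> "ElasticScanSet":
        """Sub-set holding all temperatures at one pressure, sorted by T."""
        idx = [i for i, c in enumerate(self.conditions) if np.isclose(c.pressure, pressure)]
        if not idx:
            raise KeyError(f"no conditions at P={pressure} bar")
        idx.sort(key=lambda i: self.conditions[i].temperature)
        return ElasticScanSet(
            q=self.q,
            conditions=[self.conditions[i] for i in idx],
            intensity=self.intensity[idx],
            sigma=self.sigma[idx],
            mask=self.mask.copy(),
        )


@dataclass
class QensDataset:
    """S(q, ω) maps with errors and a matched resolution measurement.

    ``s_qw`` and ``sigma`` have shape (n_conditions, n_q, n_omega);
    ``resolution`` holds one area-normalized ω-profile per q channel with its
    own 1-σ errors.
    """

    q: np.ndarray
    omega: np.ndarray
    s_qw: np.ndarray
    sigma: np.ndarray
    resolution: np.ndarray
    conditions: list[Condition]
    resolution_sigma: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.s_qw = np.asarray(self.s_qw, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.resolution = np.atleast_2d(np.asarray(self.resolution, dtype=float))
        if self.resolution_sigma is None:
            self.resolution_sigma = np.zeros_like(self.resolution)
        self.resolution_sigma = np.atleast_2d(np.asarray(self.resolution_sigma, dtype=float))
        self.validate()

    @property
    def d_omega(self) -> float:
        return float(self.omega[1] - self.omega[0])

    def validate(self) -> None:
        if self.omega.size < 3:
            raise ValidationError("omega grid needs at least 3 points")
        steps = np.diff(self.omega)
        if np.any(np.abs(steps - steps[0]) > 1e-6 * np.abs(steps[0])):
            raise FormatError("omega grid is not evenly spaced (beyond 1e-6 relative)")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing")
        n_c, n_q, n_w = len(self.conditions), self.q.size, self.omega.size
        if self.s_qw.shape != (n_c, n_q, n_w) or self.sigma.shape != (n_c, n_q, n_w):
            raise ValidationError(
                f"s_qw/sigma must have shape {(n_c, n_q, n_w)}, got "
                f"{self.s_qw.shape} and {self.sigma.shape}"
            )
        if self.resolution.shape != (n_q, n_w):
            raise ValidationError(f"resolution must have shape {(n_q, n_w)}")
        area = self.resolution.sum(axis=1) * self.d_omega
        if np.any(np.abs(area - 1.0) > 1e-6):
            raise ValidationError(
                "resolution profiles must integrate to 1 +- 1e-6 "
                "(use normalize_resolution to repair on load)"
            )

    def normalize_resolution(self) -> None:
        """Re-scale each resolution profile to unit area on its grid."""
        area = self.resolution.sum(axis=1, keepdims=True) * self.d_omega
        if np.any(area <= 0):
            raise ValidationError("resolution profile with non-positive area")
        self.resolution = self.resolution / area
        self.resolution_sigma = self.resolution_sigma / area

    def select_condition(self, temperature: float, pressure: float) -> "QensDataset":
        for i, c in enumerate(self.conditions):
            if np.isclose(c.temperature, temperature) and np.isclose(c.pressure, pressure):
                return QensDataset(
                    q=self.q,
                    omega=self.omega,
                    s_qw=self.s_qw[i : i + 1],
                    sigma=self.sigma[i : i + 1],
                    resolution=self.resolution,
                    resolution_sigma=self.resolution_sigma,
                    conditions=[c],
                )
        raise KeyError(f"no condition at T={temperature} K, P={pressure} bar")


_POLARITY_DEFAULT = {
    "D": "acidic", "E": "acidic",
    "K": "basic", "R": "basic", "H": "basic",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar",
    "C": "polar", "Y": "polar", "G": "polar",
    "A": "hydrophobic", "V": "hydrophobic", "L": "hydrophobic",
    "I": "hydrophobic", "M": "hydrophobic", "F": "hydrophobic",
    "W": "hydrophobic", "P": "hydrophobic",
}


@dataclass(frozen=True)
class SubstitutionRecord:
    """One aligned mismatch between two ortholog sequences, e.g. ``I35V``."""

    position: int  # 1-based index on the first sequence
    from_res: str
    to_res: str
    class_from: str = ""
    class_to: str = ""

    def __post_init__(self) -> None:
        if self.from_res == self.to_res:
            raise ValidationError("substitution requires from_res != to_res")

    @property
    def label(self) -> str:
        return f"{self.from_res}{self.position}{self.to_res}"


# ---------------------------------------------------------------------------
# TSV dialect (elastic scans)
# ---------------------------------------------------------------------------

def write_elastic_table(data: ElasticScanSet, path) -> str:
    """Write an ElasticScanSet to the TSV dialect; bit-stable for equal input."""
    data.validate()
    lines = [
        f"# piezodyn elastic table {FORMAT_VERSION}",
        "# units: T=K P=bar q=1/angstrom intensity=arb sigma=arb",
        "# mask: " + "".join("1" if m else "0" for m in data.mask),
        "\t".join(_ELASTIC_COLUMNS),
    ]
    for cond, inten, sig in zip(data.conditions, data.intensity, data.sigma):
        for qi, ii, si in zip(data.q, inten, sig):
            lines.append(
                f"{float(cond.temperature)!r}\t{float(cond.pressure)!r}\t"
                f"{float(qi)!r}\t{float(ii)!r}\t{float(si)!r}"
            )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def read_elastic_table(path) -> ElasticScanSet:
    """Read the TSV dialect back into a validated ElasticScanSet."""
    mask_line = None
    with open(path, encoding="utf-8") as fh:
        header: list[str] = []
        for line in fh:
            if line.startswith("#"):
                header.append(line)
                if line.startswith("# mask:"):
                    mask_line = line.split(":", 1)[1].strip()
            else:
                break
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse elastic table {path}: {exc}") from exc
    for col in _ELASTIC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"elastic table {path} is missing column '{col}'")
    if np.any(df["sigma"].to_numpy() <= 0):
        raise ValidationError("sigma column must be strictly positive")

    groups = df.groupby(["T", "P"], sort=True)
    q_ref = None
    conditions, inten_rows, sig_rows = [], [], []
    for (t, p), g in groups:
        g = g.sort_values("q")
        q = g["q"].to_numpy(dtype=float)
        if q_ref is None:
            q_ref = q
        elif q.shape != q_ref.shape or np.any(q != q_ref):
            raise FormatError("all (T, P) groups must share the same q grid")
        conditions.append(Condition(float(t), float(p)))
        inten_rows.append(g["intensity"].to_numpy(dtype=float))
        sig_rows.append(g["sigma"].to_numpy(dtype=float))
    mask = None
    if mask_line is not None and q_ref is not None and len(mask_line) == q_ref.size:
        mask = np.array([c == "1" for c in mask_line], dtype=bool)
    return ElasticScanSet(
        q=q_ref,
        conditions=conditions,
        intensity=np.vstack(inten_rows),
        sigma=np.vstack(sig_rows),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# HDF5 store (QENS maps + resolution)
# ---------------------------------------------------------------------------

def write_qens_store(data: QensDataset, path) -> str:
    """Write a QensDataset to the HDF5 layout; bit-stable for equal input."""
    data.validate()

    def _ds(grp, name, arr):
        # track_times=False keeps the byte stream independent of wall time
        grp.create_dataset(name, data=np.asarray(arr, dtype=float), track_times=False)

    with h5py.File(path, "w", track_order=False) as h5:
        h5.attrs["format"] = FORMAT_VERSION
        qg = h5.create_group("qens")
        _ds(qg, "q", data.q)
        _ds(qg, "omega", data.omega)
        _ds(qg, "S", data.s_qw)
        _ds(qg, "sigma", data.sigma)
        _ds(qg, "T", [c.temperature for c in data.conditions])
        _ds(qg, "P", [c.pressure for c in data.conditions])
        rg = h5.create_group("resolution")
        _ds(rg, "q", data.q)
        _ds(rg, "omega", data.omega)
        _ds(rg, "R", data.resolution)
        _ds(rg, "sigma", data.resolution_sigma)
    return str(path)


def read_qens_store(path) -> QensDataset:
    """Read the HDF5 store; resolution profiles are re-normalized on load."""
    try:
        with h5py.File(path, "r") as h5:
            if "qens" not in h5:
                raise FormatError(f"{path}: missing /qens group")
            if "resolution" not in h5:
                raise FormatError(
                    f"{path}: missing /resolution group — supply a vanadium "
                    "resolution measurement"
                )
            qg, rg = h5["qens"], h5["resolution"]
            data = QensDataset(
                q=qg["q"][()],
                omega=qg["omega"][()],
                s_qw=qg["S"][()],
                sigma=qg["sigma"][()],
                resolution=_normalized(rg["R"][()], qg["omega"][()]),
                resolution_sigma=rg["sigma"][()],
                conditions=[
                    Condition(float(t), float(p))
                    for t, p in zip(qg["T"][()], qg["P"][()])
                ],
            )
    except OSError as exc:
        raise FormatError(f"cannot open QENS store {path}: {exc}") from exc
    return data


def _normalized(res: np.ndarray, omega: np.ndarray) -> np.ndarray:
    res = np.atleast_2d(np.asarray(res, dtype=float))
    d_omega = float(omega[1] - omega[0])
    area = res.sum(axis=1, keepdims=True) * d_omega
    if np.any(area <= 0):
        raise ValidationError("resolution profile with non-positive area")
    return res / area
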