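"""Functional-connectivity edge estimators for node-level BOLD time series.

Two edge definitions are provided for a pair of time series ``x``, ``y``:

``pearson_abs``
    The absolute sample Pearson correlation ``|r|``.

``grid_mi``
    A grid-maximised mutual information.  The joint sample is discretised on a
    3x3 grid; per axis the outer bin boundaries are the series minimum and
    maximum and the middle two boundaries sit at ``mean - m_low*SD`` and
    ``mean + m_up*SD`` for multiples drawn from a small fixed family.  MI is
    computed from the 3x3 frequency counts (natural log, so the jointly
    Gaussian closed form is -1/2 ln(1 - r^2)) and the reported edge weight is
    the maximum over all candidate grids.  With the default five multiples this
    is a family of 25 middle-boundary pairs per axis and 125 candidate grids
    per node pair (the lower multiple is shared between axes, the two upper
    multiples are free; the family is closed under axis swap).  This is a
    fixed-resolution relative of the maximal information coefficient: MIC
    maximises over all resolutions, which is infeasible for the ~3e5 node
    pairs of a whole-brain graph, so the resolution is pinned at 3x3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LN3",
    "DEFAULT_MULTIPLES",
    "DegenerateSeriesError",
    "MiConfig",
    "GridSpec",
    "ContingencyTable",
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "pearson_edge",
    "axis_boundary_pairs",
    "enumerate_grids",
    "contingency_counts",
    "mi_from_counts",
    "grid_mi",
    "gaussian_reference",
    "connectivity_matrix",
    "write_connectivity",
    "read_connectivity",
]

#: Upper bound of the 3x3 mutual information, in nats.
LN3 = math.log(3.0)

#: Default family of standard-deviation multiples for the middle boundaries.
DEFAULT_MULTIPLES = (0.25, 0.5, 0.75, 1.0, 1.25)

METHODS = ("pearson_abs", "grid_mi")


class DegenerateSeriesError(ValueError):
    """A series (or every candidate grid built from it) carries no usable variation."""


@dataclass(frozen=True)
class MiConfig:
    """Configuration of the grid-maximised MI estimator.

    Parameters
    ----------
    multiples
        Strictly increasing positive SD multiples for the middle boundaries.
    resolution
        Grid resolution per axis; only 3 is supported.
    enumeration_mode
        ``"paper125"`` shares the lower multiple between the two axes
        (``k**3`` candidate grids for ``k`` multiples); ``"full"`` enumerates
        all four multiples independently (``k**4``).
    """

    multiples: tuple[float, ...] = DEFAULT_MULTIPLES
    resolution: int = 3
    enumeration_mode: str = "paper125"

    def __post_init__(self) -> None:
        m = tuple(float(v) for v in self.multiples)
        object.__setattr__(self, "multiples", m)
        if not m or any(v <= 0 for v in m):
            raise ValueError("multiples must all be positive")
        if any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("multiples must be strictly increasing")
        if self.resolution != 3:
            raise ValueError("only 3x3 grids are supported (resolution=3)")
        if self.enumeration_mode not in ("paper125", "full"):
            raise ValueError("enumeration_mode must be 'paper125' or 'full'")

    @property
    def n_candidate_grids(self) -> int:
        """Number of enumerated candidate grids per pair (before degeneracy drops)."""
        k = len(self.multiples)
        return k**3 if self.enumeration_mode == "paper125" else k**4

    @property
    def n_axis_boundary_pairs(self) -> int:
        """Number of candidate (lower, upper) middle-boundary pairs per axis."""
        return len(self.multiples) ** 2


@dataclass(frozen=True)
class GridSpec:
    """One concrete 3x3 discretisation grid: four ascending boundaries per axis."""

    x_bounds: tuple[float, float, float, float]
    y_bounds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name, b in (("x_bounds", self.x_bounds), ("y_bounds", self.y_bounds)):
            b = tuple(float(v) for v in b)
            object.__setattr__(self, name, b)
            if len(b) != 4:
                raise ValueError(f"{name} must hold exactly 4 boundaries")
            if any(v2 <= v1 for v1, v2 in zip(b, b[1:])):
                raise ValueError(f"{name} must be strictly ascending")


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 joint frequency counts of a discretised series pair."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a 3x3 array of nonnegative integers")
        if int(c.sum()) != self.n:
            raise ValueError("counts must sum to n")


@dataclass
class TimeSeriesMatrix:
    """One subject's node x time BOLD signal matrix."""

    values: np.ndarray
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D node x time array")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if v.shape[1] < 10:
            raise ValueError("need at least 10 time points")
        if not np.isfinite(v).all():
            raise ValueError("values must be finite")
        self.values = v
        if self.node_ids is None:
            self.node_ids = tuple(f"n{i:03d}" for i in range(v.shape[0]))
        else:
            self.node_ids = tuple(str(t) for t in self.node_ids)
            if len(self.node_ids) != v.shape[0]:
                raise ValueError("node_ids length must match the number of rows")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node edge-weight matrix with zero diagonal."""

    weights: np.ndarray
    method: str
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not np.allclose(w, w.T, atol=1e-12, rtol=0.0):
            raise ValueError("weights must be symmetric")
        if np.diagonal(w).any():
            raise ValueError("diagonal must be zero")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        hi = 1.0 if self.method == "pearson_abs" else LN3
        if w.max(initial=0.0) > hi + 1e-9:
            raise ValueError(f"{self.method} weights must lie in [0, {hi:.4f}]")
        self.weights = w
        self.node_ids = tuple(str(t) for t in self.node_ids)
        if len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length must match the matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# Scalar estimators
# ---------------------------------------------------------------------------


def _as_series(x, name: str = "series") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 3:
        raise ValueError(f"{name} must have at least 3 samples")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} must be finite")
    return x


def _series_stats(x: np.ndarray, name: str = "series"):
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSeriesError(f"{name} is constant (zero standard deviation)")
    return float(x.mean()), sd, float(x.min()), float(x.max())


def pearson_edge(x, y) -> float:
    """Absolute sample Pearson correlation between two equal-length series."""
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    if x.size != y.size:
        raise ValueError("series must have equal length")
    _series_stats(x, "x")
    _series_stats(y, "y")
    r = float(np.corrcoef(x, y)[0, 1])
    return min(abs(r), 1.0)


def gaussian_reference(r: float) -> float:
    """MI (nats) of a bivariate Gaussian with correlation ``r``: -1/2 ln(1 - r^2)."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    return -0.5 * math.log1p(-(r * r))


def axis_boundary_pairs(x, config: MiConfig | None = None) -> np.ndarray:
    """All candidate (lower, upper) middle-boundary values for one axis.

    With ``k`` multiples there are ``k**2`` pairs ``(mean - m_i*SD,
    mean + m_j*SD)``; degenerate pairs (outside the open data range) are
    included here and dropped at grid-enumeration time.
    """
    config = config or MiConfig()
    x = _as_series(x, "x")
    mean, sd, _, _ = _series_stats(x, "x")
    m = np.asarray(config.multiples)
    low = mean - m * sd
    up = mean + m * sd
    pairs = np.stack(np.meshgrid(low, up, indexing="ij"), axis=-1).reshape(-1, 2)
    return pairs


def _axis_bounds(x: np.ndarray, multiples: np.ndarray, name: str):
    """Per-axis candidate boundaries and validity.

    Returns ``(low, up, mn, mx, valid)`` where ``valid[i, j]`` is True when
    ``mn < low[i] < up[j] < mx`` (strictly ascending grid after clamping).
    """
    mean, sd, mn, mx = _series_stats(x, name)
    low = mean - multiples * sd
    up = mean + multiples * sd
    valid = (low[:, None] > mn) & (up[None, :] < mx) & (low[:, None] < up[None, :])
    return low, up, mn, mx, valid


def enumerate_grids(x, y, config: MiConfig | None = None) -> list[GridSpec]:
    """Enumerate all non-degenerate candidate 3x3 grids for a series pair.

    Under ``paper125`` the lower-boundary multiple is shared between axes and
    the two upper multiples are free; grids whose boundaries are not strictly
    ascending are dropped from the returned list (they still count toward
    ``config.n_candidate_grids``).
    """
    config = config or MiConfig()
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    m = np.asarray(config.multiples)
    k = m.size
    xlow, xup, xmn, xmx, xvalid = _axis_bounds(x, m, "x")
    ylow, yup, ymn, ymx, yvalid = _axis_bounds(y, m, "y")

    grids: list[GridSpec] = []
    if config.enumeration_mode == "paper125":
        combos = (
            ((lo, ax), (lo, ay)) for lo in range(k) for ax in range(k) for ay in range(k)
        )
    else:
        combos = (
            ((lx, ax), (ly, ay))
            for lx in range(k)
            for ax in range(k)
            for ly in range(k)
            for ay in range(k)
        )
    for (lx, ax), (ly, ay) in combos:
        if not (xvalid[lx, ax] and yvalid[ly, ay]):
            continue
        grids.append(
            GridSpec(
                x_bounds=(xmn, float(xlow[lx]), float(xup[ax]), xmx),
                y_bounds=(ymn, float(ylow[ly]), float(yup[ay]), ymx),
            )
        )
    if not grids:
        raise DegenerateSeriesError("every candidate grid is degenerate for this pair")
    return grids


def _bin_labels(x: np.ndarray, bounds) -> np.ndarray:
    """Bin membership with the [b0,b1), [b1,b2), [b2,b3] convention."""
    return (x >= bounds[1]).astype(np.int64) + (x >= bounds[2])


def contingency_counts(x, y, grid: GridSpec) -> ContingencyTable:
    """3x3 joint frequency counts of ``(x, y)`` on a concrete grid."""
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    if x.size != y.size:
        raise ValueError("series must have equal length")
    for s, b, name in ((x, grid.x_bounds, "x"), (y, grid.y_bounds, "y")):
        if s.min() < b[0] or s.max() > b[3]:
            raise RuntimeError(f"{name} values fall outside the outer grid boundaries")
    lx = _bin_labels(x, grid.x_bounds)
    ly = _bin_labels(y, grid.y_bounds)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (lx, ly), 1)
    return ContingencyTable(counts=counts, n=int(x.size))


def _mi_batch(counts: np.ndarray) -> np.ndarray:
    """MI in nats for a batch of contingency tables, shape (G, 3, 3)."""
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum(axis=(1, 2), keepdims=True)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(px) - np.log(py))
    terms[counts == 0] = 0.0
    return np.maximum(terms.sum(axis=(1, 2)), 0.0)


def mi_from_counts(table: ContingencyTable) -> float:
    """Plug-in mutual information (nats) of one 3x3 contingency table.

    0*ln 0 is taken as 0; the result lies in [0, ln 3].
    """
    if table.n < 1:
        raise ValueError("table must contain at least one observation")
    return float(_mi_batch(table.counts[None])[0])


def _axis_labelings(x: np.ndarray, multiples: np.ndarray):
    """All candidate per-axis bin labelings: (k, k, T) labels plus validity mask."""
    low, up, _, _, valid = _axis_bounds(x, multiples, "series")
    labels = (x[None, None, :] >= low[:, None, None]).astype(np.int16) + (
        x[None, None, :] >= up[None, :, None]
    )
    return labels, valid


def _pair_max_mi(lab_x, valid_x, lab_y, valid_y, mode: str) -> float:
    """Maximum MI over the enumerated grids given precomputed axis labelings."""
    k, _, t = lab_x.shape
    if mode == "paper125":
        joint = 3 * lab_x[:, :, None, :] + lab_y[:, None, :, :]
        valid = valid_x[:, :, None] & valid_y[:, None, :]
    else:
        joint = (
            3 * lab_x[:, :, None, None, :] + lab_y[None, None, :, :, :]
        )
        valid = valid_x[:, :, None, None] & valid_y[None, None, :, :]
    flat = joint.reshape(-1, t).astype(np.int64)
    g = flat.shape[0]
    offs = 9 * np.arange(g, dtype=np.int64)[:, None]
    counts = np.bincount((flat + offs).ravel(), minlength=9 * g).reshape(g, 3, 3)
    mi = _mi_batch(counts)
    mi[~valid.ravel()] = -np.inf
    best = float(mi.max())
    if not np.isfinite(best):
        raise DegenerateSeriesError("every candidate grid is degenerate for this pair")
    return best


def grid_mi(x, y, config: MiConfig | None = None) -> float:
    """Grid-maximised mutual information (nats) between two series.

    Maximum of :func:`mi_from_counts` over :func:`enumerate_grids`; symmetric
    in its arguments and bounded by ln 3.
    """
    config = config or MiConfig()
    x = _as_series(x, "x")
    y = _as_series(y, "y")
    if x.size != y.size:
        raise ValueError("series must have equal length")
    m = np.asarray(config.multiples)
    lab_x, valid_x = _axis_labelings(x, m)
    lab_y, valid_y = _axis_labelings(y, m)
    return _pair_max_mi(lab_x, valid_x, lab_y, valid_y, config.enumeration_mode)


# ---------------------------------------------------------------------------
# Whole-matrix construction and I/O
# ---------------------------------------------------------------------------


def connectivity_matrix(
    ts: TimeSeriesMatrix, method: str, config: MiConfig | None = None
) -> ConnectivityMatrix:
    """Build the symmetric connectivity matrix for one subject.

    Every unordered node pair is computed once and mirrored; the diagonal is
    zero.  Constant node series are rejected with the offending node ids.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    vals = ts.values
    sds = vals.std(axis=1, ddof=1)
    bad = [nid for nid, sd in zip(ts.node_ids, sds) if sd == 0.0]
    if bad:
        raise DegenerateSeriesError(f"constant node series: {', '.join(bad)}")

    n = ts.n_nodes
    if method == "pearson_abs":
        w = np.abs(np.corrcoef(vals))
        w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
    else:
        config = config or MiConfig()
        m = np.asarray(config.multiples)
        labelings = [_axis_labelings(vals[i], m) for i in range(n)]
        w = np.zeros((n, n))
        for i in range(n):
            lab_i, val_i = labelings[i]
            for j in range(i + 1, n):
                lab_j, val_j = labelings[j]
                w[i, j] = w[j, i] = _pair_max_mi(
                    lab_i, val_i, lab_j, val_j, config.enumeration_mode
                )
    return ConnectivityMatrix(weights=w, method=method, node_ids=ts.node_ids)


def write_connectivity(cm: ConnectivityMatrix, path) -> None:
    """Write a connectivity matrix as dense TSV with a one-line header."""
    with open(path, "w") as fh:
        fh.write(f"# method={cm.method} nodes={cm.n_nodes}\n")
        for nid, row in zip(cm.node_ids, cm.weights):
            fh.write(nid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_connectivity(path) -> ConnectivityMatrix:
    """Read a connectivity matrix written by :func:`write_connectivity`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# method="):
            raise ValueError(f"{path}: missing connectivity header")
        fields = dict(tok.split("=") for tok in header[2:].split())
        method = fields["method"]
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    w = np.asarray(rows)
    if "nodes" in fields and int(fields["nodes"]) != w.shape[0]:
        raise ValueError(f"{path}: header node count does not match matrix")
    return ConnectivityMatrix(weights=w, method=method, node_ids=tuple(ids))
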