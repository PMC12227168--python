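"""Quantile specifications and contrast families.

A contrast family is an ``r x (k*m)`` matrix ``H`` whose rows ``h_l`` compare
linear combinations of the pooled quantile vector
``q = (q_11, ..., q_1m, q_21, ..., q_km)'`` across ``k`` independent groups and
``m`` probabilities.  The layout is group-major: entry ``(i-1)*m + j`` belongs
to group ``i`` and probability ``p_j``.  Every row must satisfy the contrast
property: for each probability index ``j`` the coefficients sum to zero over
the groups, so that common location shifts cancel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "QuantileSpec",
    "MEDIAN",
    "MED_IQR",
    "ContrastFamily",
    "ValidationReport",
    "make_dunnett",
    "make_tukey",
    "make_grandmean",
    "make_custom",
    "make_simultaneous_med_iqr",
    "validate_contrast_family",
]

#: selector turning the (q_0.25, q_0.5, q_0.75) block of one group into
#: (median, IQR); used by :func:`make_simultaneous_med_iqr`
_MED_IQR_SELECTOR = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])

_ZERO_SUM_TOL = 1e-10


@dataclass(frozen=True)
class QuantileSpec:
    """Ordered probabilities ``0 < p_1 < ... < p_m < 1`` with labels."""

    probabilities: tuple
    labels: tuple = None

    def __post_init__(self):
        probs = tuple(float(p) for p in self.probabilities)
        if len(probs) < 1:
            raise ValueError("at least one probability is required")
        if any(not (0.0 < p < 1.0) for p in probs):
            raise ValueError("probabilities must lie in the open interval (0, 1)")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValueError("probabilities must be strictly increasing")
        object.__setattr__(self, "probabilities", probs)
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(f"p={p:g}" for p in probs))
        elif len(self.labels) != len(probs):
            raise ValueError("labels must match probabilities in length")
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def m(self) -> int:
        return len(self.probabilities)


MEDIAN = QuantileSpec((0.5,), labels=("median",))
MED_IQR = QuantileSpec((0.25, 0.5, 0.75))


@dataclass
class ContrastFamily:
    """A set of linear contrasts of the pooled quantile vector.

    Attributes
    ----------
    matrix : ndarray, shape (r, k*m)
        Contrast rows in group-major layout.
    k, m : int
        Number of groups and probabilities per group.
    margins : ndarray, shape (r,)
        Per-row constants (noninferiority margins / null values), default 0.
    row_labels : list of str
        Human-readable contrast names.
    family_tag : str
        One of ``{"dunnett", "tukey", "grandmean", "custom", "kron"}``.
    """

    matrix: np.ndarray
    k: int
    m: int = 1
    margins: np.ndarray = None
    row_labels: list = None
    family_tag: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        r, ncol = self.matrix.shape
        if r < 1:
            raise ValueError("contrast family needs at least one row")
        if ncol != self.k * self.m:
            raise ValueError(
                f"matrix has {ncol} columns, expected k*m = {self.k * self.m}"
            )
        if self.margins is None:
            self.margins = np.zeros(r)
        self.margins = np.asarray(self.margins, dtype=float).reshape(-1)
        if self.margins.shape != (r,):
            raise ValueError("margins must have one entry per contrast row")
        if self.row_labels is None:
            self.row_labels = [f"contrast {i + 1}" for i in range(r)]
        if len(self.row_labels) != r:
            raise ValueError("row_labels must have one entry per contrast row")
        if np.any(np.all(self.matrix == 0.0, axis=1)):
            raise ValueError("contrast family contains an all-zero row")

    @property
    def r(self) -> int:
        return self.matrix.shape[0]

    def with_margins(self, margins) -> "ContrastFamily":
        """Return a copy with the given margins (scalar broadcasts)."""
        eps = np.broadcast_to(np.asarray(margins, dtype=float), (self.r,)).copy()
        return replace(self, margins=eps, row_labels=list(self.row_labels))

    def negated(self) -> "ContrastFamily":
        """Return a copy with rows and margins negated (direction flip)."""
        return replace(
            self,
            matrix=-self.matrix,
            margins=-self.margins,
            row_labels=list(self.row_labels),
        )

    # -- JSON round trip (CLI interchange) ---------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.tolist(),
                "k": self.k,
                "m": self.m,
                "margins": self.margins.tolist(),
                "row_labels": list(self.row_labels),
                "family_tag": self.family_tag,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ContrastFamily":
        d = json.loads(text)
        return cls(
            matrix=np.asarray(d["matrix"], dtype=float),
            k=int(d["k"]),
            m=int(d.get("m", 1)),
            margins=np.asarray(d["margins"], dtype=float),
            row_labels=list(d["row_labels"]),
            family_tag=d.get("family_tag", "custom"),
        )


def _check_k(k: int) -> None:
    if k < 2:
        raise ValueError("at least two groups are required (k >= 2)")


def make_dunnett(k: int, base: int = 1, labels=None) -> ContrastFamily:
    """Many-to-one contrasts: each group versus the ``base`` group.

    Rows are ordered by ascending group index, skipping the base; the row for
    group ``l`` is ``q_l - q_base``.  ``base`` is 1-indexed.
    """
    _check_k(k)
    if not 1 <= base <= k:
        raise ValueError(f"base group {base} out of range 1..{k}")
    rows, names = [], []
    group_labels = labels if labels is not None else [str(i + 1) for i in range(k)]
    for ell in range(1, k + 1):
        if ell == base:
            continue
        h = np.zeros(k)
        h[ell - 1] = 1.0
        h[base - 1] = -1.0
        rows.append(h)
        names.append(f"{group_labels[ell - 1]} - {group_labels[base - 1]}")
    return ContrastFamily(
        np.vstack(rows), k=k, m=1, row_labels=names, family_tag="dunnett",
        meta={"base": base},
    )


def make_tukey(k: int, labels=None) -> ContrastFamily:
    """All-pairs contrasts ``q_l1 - q_l2`` for ``l1 > l2`` (lexicographic in l2)."""
    _check_k(k)
    rows, names = [], []
    group_labels = labels if labels is not None else [str(i + 1) for i in range(k)]
    for l2 in range(1, k + 1):
        for l1 in range(l2 + 1, k + 1):
            h = np.zeros(k)
            h[l1 - 1] = 1.0
            h[l2 - 1] = -1.0
            rows.append(h)
            names.append(f"{group_labels[l1 - 1]} - {group_labels[l2 - 1]}")
    return ContrastFamily(np.vstack(rows), k=k, m=1, row_labels=names, family_tag="tukey")


def make_grandmean(k: int, labels=None) -> ContrastFamily:
    """Each group versus the unweighted mean of all groupwise effects.

    The matrix is the centering matrix ``I_k - J_k/k`` (rank ``k - 1``).
    """
    _check_k(k)
    group_labels = labels if labels is not None else [str(i + 1) for i in range(k)]
    mat = np.eye(k) - np.full((k, k), 1.0 / k)
    names = [f"{g} - grand mean" for g in group_labels]
    return ContrastFamily(mat, k=k, m=1, row_labels=names, family_tag="grandmean")


def make_custom(matrix, k: int, m: int = 1, margins=None, row_labels=None) -> ContrastFamily:
    fam = ContrastFamily(matrix, k=k, m=m, margins=margins, row_labels=row_labels,
                         family_tag="custom")
    report = validate_contrast_family(fam, k, _spec_for_m(m))
    if not report.ok:
        raise ValueError(f"invalid contrast matrix: {report.messages}")
    return fam


def _spec_for_m(m: int) -> QuantileSpec:
    # equispaced placeholder spec; only the count matters for validation
    return QuantileSpec(tuple((j + 1) / (m + 1) for j in range(m)))


def make_simultaneous_med_iqr(base: ContrastFamily) -> ContrastFamily:
    """Expand an ``m = 1`` family into joint median + IQR contrasts.

    The Kronecker product of the base matrix with the selector
    ``[[0, 1, 0], [-1, 0, 1]]`` acts on the per-group quantile triple
    ``(q_0.25, q_0.5, q_0.75)``: the first selector row extracts the median,
    the second the IQR ``q_0.75 - q_0.25``.  The result has ``2 r`` rows over
    the probability spec ``(0.25, 0.5, 0.75)`` and inherits the contrast
    property from the base family.
    """
    if base.m != 1:
        raise ValueError("base family must be built over a single quantile (m=1)")
    mat = np.kron(base.matrix, _MED_IQR_SELECTOR)
    labels = []
    for name in base.row_labels:
        labels.append(f"median: {name}")
        labels.append(f"IQR: {name}")
    return ContrastFamily(
        mat, k=base.k, m=3, row_labels=labels, family_tag="kron",
        meta={"base_tag": base.family_tag},
    )


@dataclass
class ValidationReport:
    ok: bool
    bad_rows: list
    messages: list

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_contrast_family(family: ContrastFamily, k: int, spec: QuantileSpec) -> ValidationReport:
    """Check shape and the per-probability zero-sum contrast property.

    Report-style: never raises; offending rows are listed 1-indexed.
    """
    m = spec.m
    bad, msgs = [], []
    if family.matrix.shape[1] != k * m:
        return ValidationReport(
            False, [], [f"matrix has {family.matrix.shape[1]} columns, expected {k * m}"]
        )
    blocks = family.matrix.reshape(family.r, k, m)
    col_sums = blocks.sum(axis=1)  # (r, m): sum over groups per probability
    for ell in range(family.r):
        if np.any(np.abs(col_sums[ell]) > _ZERO_SUM_TOL):
            bad.append(ell + 1)
            msgs.append(
                f"row {ell + 1}: per-probability group sums {col_sums[ell]} != 0"
            )
        if np.all(family.matrix[ell] == 0.0):
            bad.append(ell + 1)
            msgs.append(f"row {ell + 1}: all-zero row")
    return ValidationReport(len(bad) == 0, sorted(set(bad)), msgs)
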