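"""Validation procedures: fragment clustering and rank correlations.

Energy profiles are cut into short sliding windows, each labelled by an
externally supplied per-residue category (secondary-structure class,
membrane topology region, ...).  The windows are clustered with neural
gas — labels hidden — and the agreement between clusters and labels is
measured with normalized mutual information (NMI).  Repeating the
procedure over random fragment subsamples gives a mean NMI and its
spread.  Spearman rank correlation is provided for relating dScores to
external similarity measures such as structure-alignment scores or
sequence identities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import normalized_mutual_info_score

from .errors import EprofilerError, FormatError
from .profile import EnergyProfile

DEFAULT_WINDOW = 5
DEFAULT_SAMPLE = 600
DEFAULT_REPEATS = 100


@dataclass(frozen=True)
class ProfileFragment:
    """A fixed-length energy window labelled by its center residue."""

    source_id: str
    start: int
    energies: tuple[float, ...]
    label: str


def fragment_profiles(
    profiles: Sequence[EnergyProfile],
    labels: Mapping[str, Sequence[str]],
    window: int = DEFAULT_WINDOW,
) -> list[ProfileFragment]:
    """All sliding windows (stride 1) of every profile.

    ``labels[profile.id]`` must hold one category per residue; a fragment
    takes the label of its center residue.  Profiles shorter than the
    window are skipped with a warning.
    """
    import logging

    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[ProfileFragment] = []
    for p in profiles:
        labs = labels[p.id]
        if len(labs) != len(p):
            raise EprofilerError(
                f"label vector for {p.id!r} has length {len(labs)}, "
                f"profile has {len(p)} residues"
            )
        if len(p) < window:
            logging.getLogger(__name__).warning(
                "profile %s shorter than window %d; skipped", p.id, window
            )
            continue
        e = p.energies
        for start in range(len(p) - window + 1):
            center = start + window // 2
            out.append(
                ProfileFragment(
                    source_id=p.id,
                    start=start,
                    energies=tuple(float(x) for x in e[start:start + window]),
                    label=str(labs[center]),
                )
            )
    return out


def read_labels(fh: TextIO, profile: EnergyProfile) -> list[str]:
    """Read a ``chain  seq_index  label`` TSV and order it per profile entry."""
    table: dict[tuple[str, int], str] = {}
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"line {lineno}: expected 3 columns")
        table[(fields[0], int(fields[1]))] = fields[2]
    out = []
    for e in profile.entries:
        key = (e.chain_id, e.seq_index)
        if key not in table:
            raise EprofilerError(f"no label for residue {key}")
        out.append(table[key])
    return out


def neural_gas(
    X: np.ndarray,
    k: int,
    n_iter: int | None = None,
    seed: int = 0,
    lr: tuple[float, float] = (0.5, 0.005),
    neighborhood: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Neural-gas vector quantization; returns (assignments, prototypes).

    Prototypes adapt by distance rank with exponentially decaying
    learning rate (0.5 -> 0.005) and neighborhood range (k/2 -> 0.01)
    over ``n_iter`` sample presentations (default 50 per sample).  As
    the neighborhood range approaches zero only the winning prototype
    moves and the update reduces to online k-means.  Final assignment is
    the Euclidean-nearest prototype.
    """
    X = np.asarray(X, dtype=float)
    n, dim = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise EprofilerError(f"more prototypes ({k}) than samples ({n})")
    if n_iter is None:
        n_iter = 50 * n
    if neighborhood is None:
        neighborhood = (max(k / 2.0, 1e-2), 0.01)
    rng = np.random.default_rng(seed)
    W = X[rng.choice(n, size=k, replace=False)].copy()
    lr0, lr1 = lr
    lam0, lam1 = neighborhood
    denom = max(n_iter - 1, 1)
    ranks_buf = np.empty(k)
    for t in range(n_iter):
        x = X[rng.integers(n)]
        d = np.linalg.norm(W - x, axis=1)
        order = np.argsort(d, kind="stable")
        ranks_buf[order] = np.arange(k)
        eps = lr0 * (lr1 / lr0) ** (t / denom)
        lam = lam0 * (lam1 / lam0) ** (t / denom)
        W += (eps * np.exp(-ranks_buf / lam))[:, None] * (x - W)
    d = np.linalg.norm(X[:, None, :] - W[None, :, :], axis=2)
    return d.argmin(axis=1), W


def nmi(labels_a: Sequence, labels_b: Sequence,
        average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two labelings.

    Arithmetic-mean normalization by default — I(A;B) / ((H(A)+H(B))/2);
    ``min``, ``max`` and ``geometric`` are accepted as alternatives.
    1.0 for identical partitions, 0.0 when either partition is constant
    or the partitions are independent.
    """
    if len(labels_a) != len(labels_b):
        raise EprofilerError("label vectors differ in length")
    if len(labels_a) == 0:
        raise EprofilerError("empty labelings")
    return float(
        normalized_mutual_info_score(labels_a, labels_b,
                                     average_method=average_method)
    )


@dataclass
class ClusteringSummary:
    mean_nmi: float
    sd_nmi: float
    values: list[float]
    k: int
    n_sample: int
    repeats: int


def repeat_clustering(
    fragments: Sequence[ProfileFragment],
    k: int | None = None,
    n_sample: int = DEFAULT_SAMPLE,
    repeats: int = DEFAULT_REPEATS,
    n_iter: int | None = None,
    seed: int = 0,
) -> ClusteringSummary:
    """Repeated subsample-cluster-evaluate cycles.

    Each repeat draws ``n_sample`` fragments at random (all of them when
    fewer are available), clusters their energy windows with neural gas
    (labels hidden) and scores the assignment against the held-out labels
    with NMI; the summary reports mean and standard deviation.  ``k``
    defaults to the number of distinct labels.
    """
    if not fragments:
        raise EprofilerError("no fragments")
    X_all = np.array([f.energies for f in fragments], dtype=float)
    y_all = np.array([f.label for f in fragments])
    if k is None:
        k = len(set(y_all))
    rng = np.random.default_rng(seed)
    values = []
    for r in range(max(1, repeats)):
        if len(fragments) > n_sample:
            idx = rng.choice(len(fragments), size=n_sample, replace=False)
        else:
            idx = np.arange(len(fragments))
        sub_seed = int(rng.integers(2**31 - 1))
        assign, _ = neural_gas(X_all[idx], k=k, n_iter=n_iter, seed=sub_seed)
        values.append(nmi(y_all[idx], assign))
    arr = np.asarray(values)
    return ClusteringSummary(
        mean_nmi=float(arr.mean()),
        sd_nmi=float(arr.std(ddof=0)),
        values=values,
        k=k,
        n_sample=min(n_sample, len(fragments)),
        repeats=max(1, repeats),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EprofilerError("vectors differ in length")
    if x.size < 3:
        raise EprofilerError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise EprofilerError("correlation undefined for a constant vector")
    rho = spearmanr(x, y).statistic
    return float(rho)
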