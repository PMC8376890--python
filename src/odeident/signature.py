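"""Identifiability signature: SVD of the sensitivity matrix, gap detection
and extraction of candidate unidentifiable unknowns.

The numeric rank test writes ``S = sum_i u_i sigma_i v_i^T`` and declares the
singular values that fall beyond a distinct gap in the log spectrum to be
numerically zero (default gap width: 10 decades).  The unknowns carrying
non-negligible components in the right singular vectors beyond the gap form
the candidate unidentifiable set, to be confirmed symbolically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .sensitivity import SensitivityMatrix

__all__ = [
    "Signature",
    "decompose",
    "detect_gap",
    "extract_candidates",
    "compute_signature",
    "render_report",
    "DegenerateSpectrumError",
]

#: defaults for the two numeric thresholds of the gap rule
DEFAULT_MIN_DECADES = 10.0
DEFAULT_COMPONENT_THRESHOLD = 1e-5


class DegenerateSpectrumError(ValueError):
    """All singular values are zero; the gap rule is meaningless."""


@dataclass(frozen=True)
class Signature:
    """Outcome of the numeric screening step.

    ``gap_index`` is the number of singular values retained above the gap
    (``None`` when no qualifying gap exists); ``singular_values[gap_index:]``
    are the numerically zero ones.  ``supports`` lists, per beyond-gap right
    singular vector, the unknowns with above-threshold components;
    ``candidates`` is their union in unknown order.
    """

    labels: tuple[str, ...]
    singular_values: tuple[float, ...]
    gap_index: int | None
    gap_decades: float | None
    null_vectors: tuple[tuple[float, ...], ...]
    supports: tuple[tuple[str, ...], ...]
    candidates: tuple[str, ...]
    min_decades: float
    component_threshold: float
    multiple_gaps: bool = False

    @property
    def identifiable(self) -> bool:
        return self.gap_index is None

    @property
    def n_zero_singular_values(self) -> int:
        return 0 if self.gap_index is None else len(self.singular_values) - self.gap_index

    def flag_of(self, label: str) -> str:
        return "candidate-unidentifiable" if label in self.candidates else "identifiable"


def decompose(S: SensitivityMatrix | np.ndarray):
    """Full SVD of the sensitivity matrix.

    Returns ``(singular_values, V)`` with ``V`` holding the right singular
    vectors as columns, ordered by descending singular value.
    """
    A = np.asarray(getattr(S, "values", S), dtype=float)
    if A.size == 0:
        raise ValueError("empty sensitivity matrix")
    _, sv, Vt = np.linalg.svd(A, full_matrices=False)
    return sv, Vt.T


def detect_gap(singular_values, min_decades: float = DEFAULT_MIN_DECADES):
    """Find the first gap of at least ``min_decades`` decades, scanning the
    descending spectrum from the largest value.

    Returns ``(gap_index, gap_decades, multiple)``: values from position
    ``gap_index`` on are numerically zero; ``gap_index is None`` when no gap
    qualifies.  ``multiple`` is True when more than one ratio qualifies (the
    first from the top is used, retaining the largest rank).
    """
    sv = np.asarray(singular_values, dtype=float)
    if len(sv) == 0 or np.all(sv == 0.0):
        raise DegenerateSpectrumError("degenerate spectrum: all singular values are zero")
    if np.any(np.diff(sv) > 0):
        raise ValueError("singular values must be non-increasing")
    if len(sv) < 2:
        return None, None, False
    with np.errstate(divide="ignore", invalid="ignore"):
        decades = np.log10(sv[:-1]) - np.log10(sv[1:])
    # 0/0 ratios (two exact zeros) are not gaps; nonzero/0 is an infinite gap
    decades = np.nan_to_num(decades, nan=0.0, posinf=np.inf)
    hits = np.flatnonzero(decades >= min_decades)
    if hits.size == 0:
        return None, None, False
    i = int(hits[0])
    return i + 1, float(decades[i]), hits.size > 1


def extract_candidates(null_vectors, labels,
                       component_threshold: float = DEFAULT_COMPONENT_THRESHOLD):
    """Per beyond-gap (unit-norm) right singular vector, the unknowns with
    ``|component| > threshold``; returns ``(supports, union)`` with the union
    in unknown order (distinct correlated sets are kept separate)."""
    supports = []
    union: list[str] = []
    for v in null_vectors:
        v = np.asarray(v, dtype=float)
        sup = tuple(lab for lab, c in zip(labels, v) if abs(c) > component_threshold)
        supports.append(sup)
        for lab in sup:
            if lab not in union:
                union.append(lab)
    union.sort(key=list(labels).index)
    return tuple(supports), tuple(union)


def compute_signature(S: SensitivityMatrix,
                      min_decades: float = DEFAULT_MIN_DECADES,
                      component_threshold: float = DEFAULT_COMPONENT_THRESHOLD,
                      ) -> Signature:
    """SVD + gap rule + candidate extraction in one step."""
    sv, V = decompose(S)
    gap_index, gap_decades, multiple = detect_gap(sv, min_decades)
    if gap_index is None:
        null_vectors: tuple = ()
    else:
        null_vectors = tuple(tuple(V[:, j]) for j in range(gap_index, len(sv)))
    supports, candidates = extract_candidates(null_vectors, S.labels,
                                              component_threshold)
    return Signature(
        labels=S.labels, singular_values=tuple(float(s) for s in sv),
        gap_index=gap_index, gap_decades=gap_decades,
        null_vectors=null_vectors, supports=supports, candidates=candidates,
        min_decades=min_decades, component_threshold=component_threshold,
        multiple_gaps=multiple,
    )


def render_report(sig: Signature, model=None, scenario: dict | None = None,
                  path: str | None = None, plot_path: str | None = None) -> dict:
    """Serialise a signature (plus config echo) as a JSON-ready report.

    Optionally writes the JSON to ``path`` and a two-panel signature plot
    (log singular-value spectrum; components of the beyond-gap singular
    vectors) to ``plot_path``.
    """
    report = {
        "model": getattr(model, "name", None),
        "labels": list(sig.labels),
        "singular_values": list(sig.singular_values),
        "gap_index": sig.gap_index,
        "gap_decades": sig.gap_decades,
        "multiple_gaps": sig.multiple_gaps,
        "n_zero_singular_values": sig.n_zero_singular_values,
        "null_vectors": [list(v) for v in sig.null_vectors],
        "supports": [list(s) for s in sig.supports],
        "theta_unid": list(sig.candidates),
        "identifiable": sig.identifiable,
        "thresholds": {"min_decades": sig.min_decades,
                       "component_threshold": sig.component_threshold},
        "scenario": scenario or {},
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    if plot_path is not None:
        _plot_signature(sig, plot_path)
    return report


def _plot_signature(sig: Signature, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6))
    ax1.semilogy(range(1, len(sig.singular_values) + 1),
                 [max(s, 1e-300) for s in sig.singular_values], "o")
    ax1.set_xlabel("index")
    ax1.set_ylabel(r"$\sigma_i$")
    ax1.set_title("singular values")
    if sig.gap_index is not None:
        ax1.axvline(sig.gap_index + 0.5, color="red", ls="--")
    pos = np.arange(len(sig.labels))
    width = 0.8 / max(len(sig.null_vectors), 1)
    for j, v in enumerate(sig.null_vectors):
        ax2.bar(pos + j * width, v, width=width, label=f"v{j + 1}")
    ax2.set_xticks(pos + 0.4 - width / 2)
    ax2.set_xticklabels(sig.labels, rotation=90, fontsize=7)
    ax2.set_ylabel("component")
    ax2.set_title("right singular vectors beyond the gap")
    if sig.null_vectors:
        ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
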