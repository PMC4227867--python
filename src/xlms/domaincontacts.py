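"""Domain assignment and inter-domain contact matrices.

Cross-linked positions are assigned to annotated domains (UniProt-style
inclusive ranges); segments not covered by any annotation become their own
``ua1, ua2, ...`` (unannotated-area) labels.  Contact matrices count links
per domain pair, the data behind diagonal contact plots shaded from white
(no contact) to dark grey (maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xlms.xlinkmap import CrossLink


class AnnotationError(ValueError):
    """Overlapping domains or position outside the sequence."""


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domain_name: str
    start: int  # inclusive, construct numbering
    end: int  # inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationError(f"{self.domain_name}: start > end")
        if self.start < 1:
            raise AnnotationError(f"{self.domain_name}: positions are 1-based")


@dataclass
class ContactMatrix:
    """Domain-pair link counts; ``normalized`` scales by the max count."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    intra: bool

    @property
    def normalized(self) -> np.ndarray:
        m = self.counts.max()
        return self.counts / m if m > 0 else self.counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    @property
    def total_links(self) -> int:
        if self.intra:
            return int(np.triu(self.counts).sum())
        return int(self.counts.sum())


def validate_annotations(annotations: list[DomainAnnotation]) -> None:
    """Reject overlapping domains within one protein."""
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        by_protein.setdefault(a.protein_id, []).append(a)
    for pid, doms in by_protein.items():
        doms = sorted(doms, key=lambda d: d.start)
        for prev, cur in zip(doms, doms[1:]):
            if cur.start <= prev.end:
                raise AnnotationError(
                    f"{pid}: domains {prev.domain_name} and {cur.domain_name} overlap"
                )


def load_annotations(path) -> list[DomainAnnotation]:
    """Read an annotation TSV (protein_id, domain, start, end); validates
    that domains within one protein do not overlap."""
    df = pd.read_csv(path, sep="\t", comment="#")
    annotations = [
        DomainAnnotation(str(r.protein_id), str(r.domain), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    validate_annotations(annotations)
    return annotations


def domain_labels(
    protein_id: str,
    annotations: list[DomainAnnotation],
    seq_len: int | None = None,
) -> list[str]:
    """Ordered row/column labels for one protein: domains by sequence
    position with ``ua`` labels inserted for the gaps (a leading gap is
    ``ua1``; a trailing gap appears only when ``seq_len`` extends past the
    last domain)."""
    doms = sorted(
        (a for a in annotations if a.protein_id == protein_id), key=lambda d: d.start
    )
    labels: list[str] = []
    ua = 0
    cursor = 1
    for d in doms:
        if d.start > cursor:
            ua += 1
            labels.append(f"ua{ua}")
        labels.append(d.domain_name)
        cursor = d.end + 1
    if seq_len is not None and seq_len >= cursor:
        ua += 1
        labels.append(f"ua{ua}")
    return labels


def assign_domain(
    protein_id: str,
    position: int,
    annotations: list[DomainAnnotation],
    seq_len: int | None = None,
) -> str:
    """Label of the domain covering ``position`` (boundaries inclusive),
    else the positional ``ua`` label of its gap."""
    if seq_len is not None and position > seq_len:
        raise AnnotationError(
            f"position {position} beyond sequence length {seq_len} of {protein_id}"
        )
    if position < 1:
        raise AnnotationError("positions are 1-based")
    doms = sorted(
        (a for a in annotations if a.protein_id == protein_id), key=lambda d: d.start
    )
    ua = 0
    cursor = 1
    for d in doms:
        if d.start > cursor:
            ua += 1
            if position < d.start:
                return f"ua{ua}"
        if d.start <= position <= d.end:
            return d.domain_name
        cursor = d.end + 1
    return f"ua{ua + 1}"


def contact_matrix(
    xls: list[CrossLink],
    annotations: list[DomainAnnotation],
    protein_row: str,
    protein_col: str,
    seq_lens: dict[str, int] | None = None,
) -> ContactMatrix:
    """Count links per domain pair.

    Intra mode (``protein_row == protein_col``) keeps links within that
    protein, counts each once in its unordered cell, and mirrors the
    matrix for display; the upper triangle (incl. diagonal) sums to the
    number of links.  Inter mode keeps links connecting the two proteins,
    rows indexing ``protein_row`` sites.
    """
    seq_lens = seq_lens or {}
    intra = protein_row == protein_col
    rows = domain_labels(protein_row, annotations, seq_lens.get(protein_row))
    cols = (
        rows if intra else domain_labels(protein_col, annotations, seq_lens.get(protein_col))
    )
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    ri = {lab: i for i, lab in enumerate(rows)}
    ci = {lab: i for i, lab in enumerate(cols)}
    for xl in xls:
        a, b = xl.site_a, xl.site_b
        if intra:
            if a.protein_id != protein_row or b.protein_id != protein_row:
                continue
            la = assign_domain(protein_row, a.position, annotations, seq_lens.get(protein_row))
            lb = assign_domain(protein_row, b.position, annotations, seq_lens.get(protein_row))
            i, j = sorted((ri[la], ri[lb]))
            counts[i, j] += 1
            if i != j:
                counts[j, i] += 1
        else:
            if {a.protein_id, b.protein_id} != {protein_row, protein_col}:
                continue
            row_site = a if a.protein_id == protein_row else b
            col_site = b if row_site is a else a
            la = assign_domain(protein_row, row_site.position, annotations, seq_lens.get(protein_row))
            lb = assign_domain(protein_col, col_site.position, annotations, seq_lens.get(protein_col))
            counts[ri[la], ci[lb]] += 1
    return ContactMatrix(rows, list(cols), counts, intra)


def save_matrix(cm: ContactMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t")


def plot_matrix(cm: ContactMatrix, path, title: str = "") -> None:
    """Grayscale heat map: white (no contact) to dark grey (maximum)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * len(cm.col_labels) + 2, 0.45 * len(cm.row_labels) + 2))
    ax.imshow(cm.normalized, cmap="Greys", vmin=0.0, vmax=1.25, origin="upper")
    ax.set_xticks(range(len(cm.col_labels)), cm.col_labels, rotation=90)
    ax.set_yticks(range(len(cm.row_labels)), cm.row_labels)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
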