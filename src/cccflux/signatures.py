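"""Ion-binding-site signature classification of CCC-family sequences.

Structures of animal cation-chloride cotransporters locate one K+ site,
two Cl- sites and -- in NKCC/NCC proteins only -- a Na+ site in the
transmembrane domain.  The Na+ site is built by two short motifs; in
Na+-coupled transporters these read LNIW (or LNIL/LNIF) and ATLSS, while
K+-Cl- cotransporters and plant CCCs carry QNIL and STLGA in the
equivalent positions and thus lack the Na+ site.  Presence or absence of
the Na+-site motifs therefore classifies a family member as NKCC-like or
KCC-like directly from an alignment.

Positions are anchored in the reference sequence's own residue numbering
(1-based, grapevine VvCCC coordinates by default) and mapped through the
alignment, so the catalog applies to any gapped MSA containing the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

GAP = "-"

Classification = Literal["KCC_like", "NKCC_like", "ambiguous"]


class AlignmentError(ValueError):
    """Invalid alignment or catalog input."""


@dataclass(frozen=True)
class MotifSite:
    """One reference-anchored site: contiguous or scattered positions plus
    the residue patterns that identify each transporter class there."""

    name: str
    positions: tuple[int, ...]  # 1-based residue indices in the reference
    kcc_motifs: tuple[str, ...] = ()
    nkcc_motifs: tuple[str, ...] = ()
    discriminative: bool = False  # True for Na+-site motifs that decide the class

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.positions):
            raise AlignmentError(f"site {self.name}: positions must be 1-based (>= 1)")
        if list(self.positions) != sorted(set(self.positions)):
            raise AlignmentError(f"site {self.name}: positions must be strictly increasing")
        for m in self.kcc_motifs + self.nkcc_motifs:
            if len(m) != len(self.positions):
                raise AlignmentError(
                    f"site {self.name}: motif {m!r} length != number of positions"
                )


@dataclass(frozen=True)
class SiteCatalog:
    """Reference-anchored ion-binding-site positions and class signatures.

    Default positions follow grapevine VvCCC (UniProt F6HLW8) numbering:
    K+ site 148/149/233, Cl- site 2 at 151-153, Cl- site 1 at
    379-381/527, Na+ site anchors 453/456/457.  The two discriminative
    Na+-site motif windows default to 147-150 (QNIL vs LNIW/LNIL/LNIF)
    and 453-457 (STLGA vs ATLSS); these windows are package-chosen anchors
    consistent with the site positions and are user-overridable.
    """

    sites: tuple[MotifSite, ...]
    reference_id: str = ""
    mismatch_tolerance: int = 1

    @classmethod
    def default(cls, reference_id: str = "", mismatch_tolerance: int = 1) -> "SiteCatalog":
        sites = (
            MotifSite("K_site", (148, 149, 233)),
            MotifSite("SCl2", (151, 152, 153)),
            MotifSite("SCl1", (379, 380, 381, 527)),
            MotifSite(
                "Na_site_cation_window",
                (147, 148, 149, 150),
                kcc_motifs=("QNIL",),
                nkcc_motifs=("LNIW", "LNIL", "LNIF"),
                discriminative=True,
            ),
            MotifSite(
                "Na_site_serine_window",
                (453, 454, 455, 456, 457),
                kcc_motifs=("STLGA",),
                nkcc_motifs=("ATLSS",),
                discriminative=True,
            ),
        )
        return cls(sites=sites, reference_id=reference_id, mismatch_tolerance=mismatch_tolerance)

    def max_position(self) -> int:
        return max(p for s in self.sites for p in s.positions)


@dataclass
class AlignedFamily:
    """A multiple sequence alignment with a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(map(len, self.rows))) > 1:
            raise AlignmentError("alignment rows are not equal length")
        if self.reference_id not in self.ids:
            raise AlignmentError(f"reference {self.reference_id!r} not in alignment")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise AlignmentError(f"sequence {seq_id!r} not in alignment") from None

    @classmethod
    def from_fasta(cls, path, reference_id: str) -> "AlignedFamily":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise AlignmentError(f"no sequences in {path}")
        return cls([r.id for r in recs], [str(r.seq) for r in recs], reference_id)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def map_reference_positions(
    family: AlignedFamily, positions: Sequence[int]
) -> list[int]:
    """Map 1-based reference residue indices to 0-based alignment columns.

    Column c holds the reference's p-th non-gap residue.
    """
    ref = family.row(family.reference_id)
    residue_to_col: dict[int, int] = {}
    res_idx = 0
    for col, ch in enumerate(ref):
        if ch != GAP:
            res_idx += 1
            residue_to_col[res_idx] = col
    out = []
    for p in positions:
        if p < 1 or p > res_idx:
            raise AlignmentError(
                f"reference position {p} out of range (reference has {res_idx} residues)"
            )
        out.append(residue_to_col[p])
    return out


def _motif_distance(observed: str, motifs: Iterable[str]) -> int:
    """Minimum Hamming distance from the observed window to any class motif."""
    if GAP in observed:
        return len(observed) + 1
    return min(sum(a != b for a, b in zip(observed, m)) for m in motifs)


def classify_sequence(
    family: AlignedFamily, seq_id: str, catalog: SiteCatalog | None = None
) -> dict:
    """Classify one aligned sequence as KCC-like or NKCC-like.

    Na+-site motif evidence decides the call: KCC-type motifs (QNIL +
    STLGA) at both discriminative windows give ``KCC_like``; NKCC-type
    motifs (LNIW/LNIL/LNIF + ATLSS) give ``NKCC_like``; conflicting or
    gap-obscured windows give ``ambiguous``.  Non-discriminative sites
    (K+ and Cl- sites, conserved across both classes) are reported as
    supporting evidence only.

    Returns ``{"class": ..., "evidence": {site name: observed residues and
    per-class match flags}}``.
    """
    catalog = catalog or SiteCatalog.default(reference_id=family.reference_id)
    row = family.row(seq_id)
    evidence: dict[str, dict] = {}
    kcc_votes = nkcc_votes = decided_windows = 0
    for site in catalog.sites:
        cols = map_reference_positions(family, site.positions)
        observed = "".join(row[c] for c in cols)
        entry: dict = {"observed": observed}
        if site.discriminative:
            kd = _motif_distance(observed, site.kcc_motifs)
            nd = _motif_distance(observed, site.nkcc_motifs)
            # a class matches when within tolerance AND strictly closer than
            # the rival class (an equidistant window is not decisive)
            k = kd <= catalog.mismatch_tolerance and kd < nd
            n = nd <= catalog.mismatch_tolerance and nd < kd
            entry.update(kcc_match=k, nkcc_match=n)
            decided_windows += 1
            kcc_votes += k
            nkcc_votes += n
        evidence[site.name] = entry
    if decided_windows and kcc_votes == decided_windows and nkcc_votes == 0:
        call: Classification = "KCC_like"
    elif decided_windows and nkcc_votes == decided_windows and kcc_votes == 0:
        call = "NKCC_like"
    else:
        call = "ambiguous"
    return {"class": call, "evidence": evidence}


def classify_family(family: AlignedFamily, catalog: SiteCatalog | None = None) -> dict[str, dict]:
    """Classify every non-reference handling row; returns id -> result."""
    catalog = catalog or SiteCatalog.default(reference_id=family.reference_id)
    return {sid: classify_sequence(family, sid, catalog) for sid in family.ids}


def conservation_profile(family: AlignedFamily, columns: Sequence[int]) -> list[dict]:
    """Simple per-column conservation: frequency of the modal residue.

    This is a deliberate stand-in for evolutionary-model-based conservation
    scoring (which requires an external homolog search): score = modal
    residue frequency among non-gap symbols, mapped linearly onto the
    conventional 1-9 conservation bins.  Also reports the residue
    variability set and aligned/total counts per column.
    """
    if len(family.rows) < 2:
        raise AlignmentError("conservation needs >= 2 sequences")
    out = []
    n_total = len(family.rows)
    for col in columns:
        if col < 0 or col >= family.n_columns:
            raise AlignmentError(f"column {col} out of range")
        residues = [r[col] for r in family.rows if r[col] != GAP]
        if not residues:
            out.append(
                {"column": col, "score": None, "bin": None, "variability": "",
                 "aligned": f"0/{n_total}", "note": "all-gap column"}
            )
            continue
        values, counts = np.unique(residues, return_counts=True)
        score = float(counts.max() / len(residues))
        order = np.argsort(-counts)
        out.append(
            {
                "column": col,
                "score": score,
                "bin": int(min(9, max(1, np.ceil(score * 9)))),
                "variability": ", ".join(values[order]),
                "aligned": f"{len(residues)}/{n_total}",
            }
        )
    return out
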