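"""Calmodulin variant catalog: records, lobe assignment, deduplication, filtering.

Calmodulin is a 149-residue (immature numbering, Met1 retained) EF-hand
calcium sensor encoded identically by three genes, *CALM1-3*.  Its two lobes
are functionally distinct: the N-lobe (EF-hands 1-2) binds calcium fast with
lower affinity, the C-lobe (EF-hands 3-4) slower with ~10x higher affinity
and mediates pre-association with targets such as the Ca_V1.2 IQ-domain.
Case/control burden analyses of missense carriers are therefore stratified
by lobe, which this module implements at the protein-change level.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

ALLOWED_GENES = frozenset({"CALM1", "CALM2", "CALM3"})
ALLOWED_COHORTS = frozenset({"SCZ", "control"})
N_RESIDUES = 149

#: Canonical EF-hand calcium-coordinating loop ranges (immature numbering).
EF_HAND_LOOPS = ((21, 32), (57, 68), (94, 105), (130, 141))

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_COMPACT_RE = re.compile(r"^([A-Y])(\d{1,3})([A-Y])$")
_HGVS_RE = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d{1,3})([A-Z][a-z]{2})$")


class VariantValidationError(ValueError):
    """Raised when a variant record violates catalog invariants."""


@dataclass(frozen=True)
class VariantRecord:
    """A single missense carrier observation at protein-change resolution."""

    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    cohort: str
    carrier_id: str = ""
    mpc: float | None = None
    cadd: float | None = None

    def __post_init__(self) -> None:
        if self.gene not in ALLOWED_GENES:
            raise VariantValidationError(f"unknown gene {self.gene!r}")
        if not 1 <= self.position <= N_RESIDUES:
            raise VariantValidationError(
                f"position {self.position} outside 1..{N_RESIDUES}"
            )
        if self.ref_aa == self.alt_aa:
            raise VariantValidationError("ref_aa equals alt_aa (synonymous)")
        if self.cohort not in ALLOWED_COHORTS:
            raise VariantValidationError(f"unknown cohort {self.cohort!r}")
        if self.mpc is not None and self.mpc < 0:
            raise VariantValidationError("mpc must be nonnegative")
        if self.cadd is not None and self.cadd < 0:
            raise VariantValidationError("cadd must be nonnegative")

    @property
    def protein_change(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class LobeMap:
    """Residue-interval partition of calmodulin into its two lobes.

    The default boundary places residue 82 and above in the C-lobe, the
    smallest boundary consistent with S82R being a C-lobe variant while
    T35I is an N-lobe variant.
    """

    n_lobe_range: tuple[int, int] = (1, 81)
    c_lobe_range: tuple[int, int] = (82, N_RESIDUES)
    ca_coordinating: frozenset[int] = field(
        default_factory=lambda: frozenset(
            p for lo, hi in EF_HAND_LOOPS for p in range(lo, hi + 1)
        )
    )

    def __post_init__(self) -> None:
        n_lo, n_hi = self.n_lobe_range
        c_lo, c_hi = self.c_lobe_range
        if not (n_lo == 1 and n_hi + 1 == c_lo and c_hi == N_RESIDUES):
            raise VariantValidationError(
                "lobe ranges must partition 1..149 contiguously"
            )


DEFAULT_LOBE_MAP = LobeMap()


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse compact ("R107C") or HGVS-like ("p.Arg107Cys") notation."""
    text = text.strip()
    m = _COMPACT_RE.match(text)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _HGVS_RE.match(text)
    if m:
        try:
            ref = AA3_TO_1[m.group(1)]
            alt = AA3_TO_1[m.group(3)]
        except KeyError as exc:
            raise VariantValidationError(
                f"unknown amino-acid code in {text!r}"
            ) from exc
        return ref, int(m.group(2)), alt
    raise VariantValidationError(f"cannot parse protein change {text!r}")


def assign_lobe(v: VariantRecord, m: LobeMap = DEFAULT_LOBE_MAP) -> str:
    """Assign a variant to "N-lobe" or "C-lobe" by residue position."""
    n_lo, n_hi = m.n_lobe_range
    if n_lo <= v.position <= n_hi:
        return "N-lobe"
    return "C-lobe"


def is_ca_coordinating(v: VariantRecord, m: LobeMap = DEFAULT_LOBE_MAP) -> bool:
    """Annotation only: whether the position is an EF-hand loop residue."""
    return v.position in m.ca_coordinating


def dedupe_variants(
    records: Sequence[VariantRecord],
    key: str = "gene",
) -> list[tuple[tuple, int]]:
    """Collapse carrier records to unique variants with multiplicities.

    ``key="gene"`` (default) deduplicates on (gene, position, ref, alt);
    ``key="substitution"`` ignores the gene, collapsing identical protein
    changes across CALM1-3.  Multiplicities sum to ``len(records)``.
    """
    if key == "gene":
        keyf = lambda r: (r.gene, r.position, r.ref_aa, r.alt_aa)
    elif key == "substitution":
        keyf = lambda r: (r.position, r.ref_aa, r.alt_aa)
    else:
        raise ValueError(f"unknown dedup key {key!r}")
    counts: Counter = Counter(keyf(r) for r in records)
    return sorted(counts.items(), key=lambda kv: kv[0][-3:])


def filter_by_mpc(
    records: Sequence[VariantRecord], threshold: float
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split records into (mpc >= threshold, mpc missing).

    Records with a defined MPC below the threshold are dropped; records
    lacking an MPC score are returned separately rather than silently
    discarded, so callers can report them.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    kept = [r for r in records if r.mpc is not None and r.mpc >= threshold]
    missing = [r for r in records if r.mpc is None]
    return kept, missing


def lobe_counts(
    records: Iterable[VariantRecord], m: LobeMap = DEFAULT_LOBE_MAP
) -> pd.DataFrame:
    """Carrier counts per (cohort, lobe) — the lobe-distribution table."""
    rows = [(r.cohort, assign_lobe(r, m)) for r in records]
    df = pd.DataFrame(rows, columns=["cohort", "lobe"])
    out = (
        df.value_counts()
        .unstack(fill_value=0)
        .reindex(index=["SCZ", "control"], columns=["N-lobe", "C-lobe"])
        .fillna(0)
        .astype(int)
    )
    return out


def read_carrier_table(path) -> list[VariantRecord]:
    """Read a carrier TSV (gene, protein_change, cohort[, carrier_id, mpc, cadd])."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "protein_change", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise VariantValidationError(f"carrier table lacks columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        ref, pos, alt = parse_protein_change(str(row["protein_change"]))
        mpc = row.get("mpc")
        cadd = row.get("cadd")
        records.append(
            VariantRecord(
                gene=str(row["gene"]),
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                cohort=str(row["cohort"]),
                carrier_id=str(row.get("carrier_id", i)),
                mpc=None if pd.isna(mpc) else float(mpc),
                cadd=None if pd.isna(cadd) else float(cadd),
            )
        )
    return records


def records_with_lobe(
    records: Sequence[VariantRecord], m: LobeMap = DEFAULT_LOBE_MAP
) -> pd.DataFrame:
    """Tabulate records with their lobe assignment (one row per carrier)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "protein_change": [r.protein_change for r in records],
            "cohort": [r.cohort for r in records],
            "carrier_id": [r.carrier_id for r in records],
            "lobe": [assign_lobe(r, m) for r in records],
            "mpc": [r.mpc for r in records],
            "cadd": [r.cadd for r in records],
        }
    )
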