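"""Bundled reference inputs for the SCHEMA calmodulin burden analysis.

The carrier fixture is *synthetic*: the published analysis reports cohort
sizes (24,248 schizophrenia cases, 97,322 controls), the per-gene/per-lobe
carrier margins, and a subset of named variants; the full carrier list is
not public.  ``schema_carriers()`` reconstructs a carrier table that matches
every printed margin (27 carriers, 25 unique variants, the 8-carrier
MPC>=2 subset split 4 SCZ C-lobe / 4 control N-lobe), filling the unnamed
control N-lobe entries with placeholder substitutions consistent with the
calmodulin sequence.  All burden statistics depend only on the margins.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import catalog

SCZ_COHORT_SIZE = 24_248
CONTROL_COHORT_SIZE = 97_322


def schema_carriers() -> list[catalog.VariantRecord]:
    """The 27-carrier synthetic SCHEMA fixture (see module docstring)."""
    ref = resources.files("calmlobe.data") / "schema_carriers_synthetic.tsv"
    with resources.as_file(ref) as path:
        return catalog.read_carrier_table(path)


def schema_cohort_sizes() -> dict[str, int]:
    return {"SCZ": SCZ_COHORT_SIZE, "control": CONTROL_COHORT_SIZE}


def schema_strata_counts(
    records=None,
    lobe_map: catalog.LobeMap = catalog.DEFAULT_LOBE_MAP,
) -> pd.DataFrame:
    """Carrier counts for the 12 burden strata (3 genes + combined, each
    overall/N-lobe/C-lobe), as a tidy frame with cohort totals attached."""
    if records is None:
        records = schema_carriers()
    df = catalog.records_with_lobe(records, lobe_map)
    rows = []
    gene_groups = [("CALM1+2+3", None), ("CALM1", "CALM1"),
                   ("CALM2", "CALM2"), ("CALM3", "CALM3")]
    for label, gene in gene_groups:
        sub = df if gene is None else df[df["gene"] == gene]
        for stratum, mask in [
            (label, slice(None)),
            (f"{label} N-lobe", sub["lobe"] == "N-lobe"),
            (f"{label} C-lobe", sub["lobe"] == "C-lobe"),
        ]:
            part = sub if isinstance(mask, slice) else sub[mask]
            rows.append(
                {
                    "stratum": stratum,
                    "cases_carriers": int((part["cohort"] == "SCZ").sum()),
                    "cases_total": SCZ_COHORT_SIZE,
                    "controls_carriers": int((part["cohort"] == "control").sum()),
                    "controls_total": CONTROL_COHORT_SIZE,
                }
            )
    return pd.DataFrame(rows)
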