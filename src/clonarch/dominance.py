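"""Driver dominance ("self-sufficiency") scoring.

The idea: a driver gene that usually appears with no or few co-occurring
driver mutations is genetically self-sufficient — it tends to be enough, on
its own, to sustain a tumor.  For gene i with carriers j = 1..N_i (patients
with a non-silent mutation in i) and d_j the number of mutated driver genes
in patient j, the dominance score is

    D_i = (sum over carriers of 1/d_j) / N_i

i.e. the mean reciprocal co-driver burden of its carriers.  D_i = 1 means
every carrier has gene i as their only mutated driver; more co-drivers pull
D_i toward 0.  Genes mutated in fewer than ``min_carriers`` patients are
excluded from the ranking (scores on a handful of carriers are noise).

By default d_j counts distinct mutated driver *genes* (two mutations in one
gene count once), which keeps hypermutated cases from deflating every score;
``count_events=True`` switches to counting mutation events.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .types import DriverCatalog, VariantRecord


def driver_burden(
    variants: Iterable[VariantRecord],
    catalog: DriverCatalog,
    gene_set: str = "luad",
    count_events: bool = False,
) -> dict[str, int]:
    """Per-patient driver burden d_j: mutated driver genes (or events) with a
    non-silent mutation, for every patient in the input."""
    drivers = catalog.genes(gene_set)
    per_patient_genes: dict[str, list[str]] = {}
    for v in variants:
        per_patient_genes.setdefault(v.patient_id, [])
        if v.effect == "non_silent" and v.gene in drivers:
            per_patient_genes[v.patient_id].append(v.gene)
    return {
        patient: (len(genes) if count_events else len(set(genes)))
        for patient, genes in per_patient_genes.items()
    }


def carrier_map(
    variants: Iterable[VariantRecord],
    catalog: DriverCatalog,
    gene_set: str = "luad",
) -> dict[str, set[str]]:
    """Gene -> set of patients carrying a non-silent mutation in it."""
    drivers = catalog.genes(gene_set)
    carriers: dict[str, set[str]] = {}
    for v in variants:
        if v.effect == "non_silent" and v.gene in drivers:
            carriers.setdefault(v.gene, set()).add(v.patient_id)
    return carriers


def dominance_scores(
    burdens: dict[str, int],
    carriers: dict[str, set[str]],
    min_carriers: int = 5,
) -> pd.DataFrame:
    """Dominance table: gene, carrier count N, score D and rank.

    Genes with fewer than ``min_carriers`` carriers are excluded.  Rank is
    by descending D, ties broken by descending N then gene name.
    """
    rows = []
    for gene, patients in carriers.items():
        n = len(patients)
        if n < min_carriers:
            continue
        for j in patients:
            if burdens.get(j, 0) < 1:
                raise ValueError(
                    f"carrier {j} of {gene} has driver burden 0: "
                    "burdens and carriers are inconsistent"
                )
        d = sum(1.0 / burdens[j] for j in patients) / n
        rows.append({"gene": gene, "N": n, "D": d})
    df = pd.DataFrame(rows, columns=["gene", "N", "D"])
    if len(df):
        df = df.sort_values(
            ["D", "N", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
        df["rank"] = df.index + 1
    else:
        df["rank"] = pd.Series(dtype=int)
    return df


def dominance_table(
    variants: Iterable[VariantRecord],
    catalog: DriverCatalog,
    gene_set: str = "luad",
    min_carriers: int = 5,
    count_events: bool = False,
) -> pd.DataFrame:
    """Convenience: burden + carrier map + scoring from a cohort mutation
    table in one call."""
    variants = list(variants)
    burdens = driver_burden(variants, catalog, gene_set, count_events)
    carriers = carrier_map(variants, catalog, gene_set)
    return dominance_scores(burdens, carriers, min_carriers)
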