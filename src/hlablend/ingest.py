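"""Readers and writers for imputation outputs and interchange tables.

Three input families are supported:

* VCF (v4.x) of binary HLA-allele markers with a per-sample genotype-
  probability triple (``GP``) — the output style of binary-marker
  imputation pipelines. Non-HLA markers (ordinary SNPs) are skipped.
* A normalised TSV interchange table of presence posteriors
  (``sample_id, allele, posterior``) or raw triples
  (``sample_id, allele, p_ref_hom, p_het, p_alt_hom``).
* A genotype-pair probability TSV (``sample_id, allele1, allele2, prob``)
  as produced by attribute-bagging imputation.

All tables are tab-delimited UTF-8 with a header row. Writers round-trip
losslessly with the corresponding readers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .alleles import AlleleId, Dialect, parse_allele, parse_allele_marker
from .containers import (
    PROB_SUM_TOL,
    GenotypeCall,
    GenotypeProbRecord,
    HibagGenotypeProb,
    PosteriorTable,
    TruthTable,
)
from .errors import (
    AmbiguousMarker,
    MissingProbabilityField,
    SchemaError,
    UnparseableMarker,
)

logger = logging.getLogger(__name__)

#: FORMAT tags accepted as genotype-probability triples, in preference order.
GP_LIKE_TAGS = ("GP",)


def read_genotype_prob_vcf(
    path: str | Path,
    dialect: Dialect | str = Dialect.AUTO,
    presence_allele: str = "ALT",
) -> list[GenotypeProbRecord]:
    """Read per-sample genotype-probability triples from a binary-marker VCF.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    dialect
        Marker-ID naming convention; ``auto`` detects per marker.
    presence_allele
        Which VCF allele column encodes *presence* of the HLA allele. With
        the default ``ALT`` (dosage-of-ALT convention) the VCF triple
        (hom-ref, het, hom-alt) is flipped so that the record's
        ``p_presence_hom`` is always the probability of two presence
        copies; with ``REF`` the triple is taken as-is.

    Returns
    -------
    list of GenotypeProbRecord, one per sample × HLA marker. Triples not
    summing to 1 within tolerance are renormalised and counted in a logged
    warning rather than dropped.

    Raises
    ------
    MissingProbabilityField
        If an HLA marker row carries no GP-like FORMAT field.
    """
    if presence_allele not in ("REF", "ALT"):
        raise ValueError(f"presence_allele must be REF or ALT, got {presence_allele!r}")
    records: list[GenotypeProbRecord] = []
    n_renormalised = 0
    n_skipped = 0
    vcf = VCF(str(path))
    samples = vcf.samples
    for variant in vcf:
        marker_id = variant.ID or ""
        try:
            allele = parse_allele_marker(marker_id, dialect)
        except (UnparseableMarker, AmbiguousMarker):
            n_skipped += 1
            continue
        gp = None
        for tag in GP_LIKE_TAGS:
            try:
                gp = variant.format(tag)
            except KeyError:
                gp = None
            if gp is not None:
                break
        if gp is None:
            raise MissingProbabilityField(
                f"marker {marker_id}: no genotype-probability (GP) FORMAT field"
            )
        for i, sample in enumerate(samples):
            hom_ref, het, hom_alt = (float(x) for x in gp[i][:3])
            if presence_allele == "ALT":
                presence_hom, absence_hom = hom_alt, hom_ref
            else:
                presence_hom, absence_hom = hom_ref, hom_alt
            total = presence_hom + het + absence_hom
            if abs(total - 1.0) > PROB_SUM_TOL:
                n_renormalised += 1
                if total > 0:
                    presence_hom, het, absence_hom = (
                        presence_hom / total,
                        het / total,
                        absence_hom / total,
                    )
            records.append(
                GenotypeProbRecord(sample, allele, presence_hom, het, absence_hom)
            )
    if n_skipped:
        logger.info("skipped %d non-HLA markers", n_skipped)
    if n_renormalised:
        logger.warning(
            "renormalised %d genotype-probability triples not summing to 1",
            n_renormalised,
        )
    return records


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_posterior_tsv(path: str | Path, panel_id: str | None = None) -> PosteriorTable:
    """Read a posterior interchange TSV into a :class:`PosteriorTable`.

    Accepts either the 3-column posterior schema or the 5-column triple
    schema (auto-converted to presence posteriors). The allele universe is
    the set of distinct alleles in the file.
    """
    from .merge import posterior_from_genotype_probs

    path = Path(path)
    panel_id = panel_id or path.stem
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "allele"], path)
    triple_cols = ["p_ref_hom", "p_het", "p_alt_hom"]
    if "posterior" in df.columns:
        posteriors = df["posterior"].astype(float)
        bad = posteriors[(posteriors < 0) | (posteriors > 1)]
        if len(bad):
            raise ValueError(f"{path}: posterior outside [0, 1]: {bad.iloc[0]}")
    elif all(c in df.columns for c in triple_cols):
        posteriors = df.apply(
            lambda r: posterior_from_genotype_probs(
                float(r["p_ref_hom"]), float(r["p_het"]), float(r["p_alt_hom"])
            ),
            axis=1,
        )
    else:
        raise SchemaError(
            f"{path}: need a 'posterior' column or the triple columns {triple_cols}"
        )

    values: dict[tuple[str, AlleleId], float] = {}
    universe: set[AlleleId] = set()
    sample_order: list[str] = []
    seen: set[str] = set()
    for (_, row), post in zip(df.iterrows(), posteriors):
        allele = parse_allele(row["allele"])
        sample = str(row["sample_id"])
        universe.add(allele)
        if sample not in seen:
            seen.add(sample)
            sample_order.append(sample)
        values[(sample, allele)] = float(post)
    return PosteriorTable(panel_id, frozenset(universe), values, tuple(sample_order))


def write_posteriors(table: PosteriorTable, path: str | Path) -> None:
    """Write a posterior table as the 3-column interchange TSV.

    Alleles in the universe with no value for a sample are written
    explicitly with posterior 0, so the universe round-trips.
    """
    rows = []
    if not table.values:
        logger.warning("writing empty posterior table to %s", path)
    for sample in table.sample_ids:
        for allele in sorted(table.allele_universe):
            rows.append(
                {
                    "sample_id": sample,
                    "allele": str(allele),
                    "posterior": table.get(sample, allele),
                }
            )
    pd.DataFrame(rows, columns=["sample_id", "allele", "posterior"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_hibag_tsv(path: str | Path) -> list[HibagGenotypeProb]:
    """Read a genotype-pair probability TSV.

    Unordered pairs are deduplicated by their canonically sorted key; a
    pair listed in both orders collapses to a single record.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "allele1", "allele2", "prob"], path)
    dedup: dict[tuple[str, str, AlleleId, AlleleId], HibagGenotypeProb] = {}
    for _, row in df.iterrows():
        a1 = parse_allele(row["allele1"])
        a2 = parse_allele(row["allele2"])
        rec = HibagGenotypeProb(
            str(row["sample_id"]), a1.gene, a1, a2, float(row["prob"])
        )
        s1, s2 = rec.sorted_pair
        key = (rec.sample_id, rec.gene, s1, s2)
        if key in dedup:
            logger.warning(
                "%s: duplicate pair (%s, %s) for %s; keeping first",
                path, s1, s2, rec.sample_id,
            )
            continue
        dedup[key] = rec
    return list(dedup.values())


def write_calls(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    """Write genotype calls as TSV; no-calls get empty allele columns."""
    calls = list(calls)
    if not calls:
        logger.warning("writing empty call set to %s", path)
    rows = [
        {
            "sample_id": c.sample_id,
            "gene": c.gene,
            "allele_1": "" if c.allele_1 is None else str(c.allele_1),
            "allele_2": "" if c.allele_2 is None else str(c.allele_2),
            "zygosity": c.zygosity,
            "p1": c.p1,
            "p2": c.p2,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "gene", "allele_1", "allele_2", "zygosity", "p1", "p2"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_calls(path: str | Path) -> list[GenotypeCall]:
    """Read genotype calls written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    _require_columns(
        df, ["sample_id", "gene", "allele_1", "allele_2", "zygosity", "p1", "p2"], path
    )
    calls = []
    for _, row in df.iterrows():
        a1 = parse_allele(row["allele_1"]) if row["allele_1"] else None
        a2 = parse_allele(row["allele_2"]) if row["allele_2"] else None
        calls.append(
            GenotypeCall(
                str(row["sample_id"]),
                str(row["gene"]),
                a1,
                a2,
                str(row["zygosity"]),
                float(row["p1"]),
                float(row["p2"]),
            )
        )
    return calls


def read_truth_tsv(path: str | Path) -> TruthTable:
    """Read a truth TSV: sample_id, gene, allele_1, allele_2."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "gene", "allele_1", "allele_2"], path)
    records = {}
    for _, row in df.iterrows():
        a1, a2 = sorted((parse_allele(row["allele_1"]), parse_allele(row["allele_2"])))
        records[(str(row["sample_id"]), str(row["gene"]))] = (a1, a2)
    return TruthTable(records)


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    rows = [
        {"sample_id": s, "gene": g, "allele_1": str(a1), "allele_2": str(a2)}
        for (s, g), (a1, a2) in truth
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene", "allele_1", "allele_2"]).to_csv(
        path, sep="\t", index=False
    )


def write_hibag_tsv(records: Iterable[HibagGenotypeProb], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "allele1": str(r.allele1),
            "allele2": str(r.allele2),
            "prob": r.probability,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample_id", "allele1", "allele2", "prob"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_exclusions(path: str | Path) -> set[AlleleId]:
    """Read an exclusion list: one allele per line, '#' comments allowed."""
    out: set[AlleleId] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(parse_allele(line))
    return out


def read_group_map(path: str | Path) -> dict[AlleleId, str]:
    """Read a two-column allele → group mapping TSV (P-group collapsing)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["allele", "group"], path)
    return {parse_allele(r["allele"]): str(r["group"]) for _, r in df.iterrows()}


def write_frequencies_tsv(
    frequencies: dict[str, dict[AlleleId, float]], path: str | Path
) -> None:
    rows = [
        {"gene": gene, "allele": str(a), "frequency": f}
        for gene, fr in frequencies.items()
        for a, f in fr.items()
    ]
    pd.DataFrame(rows, columns=["gene", "allele", "frequency"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
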