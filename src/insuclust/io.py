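"""Readers and writers for the text formats the pipeline exchanges.

Summary statistics travel as tab-delimited tables (one long file with a
``trait`` column, or one file per trait where the trait is the file stem);
genotypes as VCF v4.2 with a per-genotype DS (dosage) field or as an
individuals x variants dosage TSV; cluster weights, scores, LD pairs and
meta-analysis results as plain TSVs.
"""

from __future__ import annotations

import glob as _glob
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .bnmf import ClusterDefinitions
from .scores import GenotypePanel, LDReference, PPSTable

SUMSTATS_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "sample_size",
]


# -- summary statistics ------------------------------------------------------


def write_summary_stats(stats: pd.DataFrame, out, per_trait: bool = False) -> list:
    """Write the long table, or one per-trait file (trait = file stem), under ``out``."""
    out = Path(out)
    written = []
    if per_trait:
        out.mkdir(parents=True, exist_ok=True)
        for trait, sub in stats.groupby("trait", sort=False):
            path = out / f"{trait}.tsv"
            sub[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)
            written.append(path)
    else:
        out.parent.mkdir(parents=True, exist_ok=True)
        stats[SUMSTATS_COLUMNS + ["trait"]].to_csv(out, sep="\t", index=False)
        written.append(out)
    return written


def read_summary_stats(source) -> pd.DataFrame:
    """Read a long-format file, a glob of per-trait files, or a directory."""
    if isinstance(source, (list, tuple)):
        paths = [Path(p) for p in source]
    else:
        p = Path(source)
        if p.is_dir():
            paths = sorted(p.glob("*.tsv"))
        elif any(ch in str(source) for ch in "*?["):
            paths = [Path(q) for q in sorted(_glob.glob(str(source)))]
        else:
            paths = [p]
    if not paths:
        raise FileNotFoundError(f"no summary-statistics files match {source!r}")
    frames = []
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        if "trait" not in df.columns:
            df["trait"] = path.stem
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# -- aligned Z matrix --------------------------------------------------------


def write_zmatrix(zmat, out_dir) -> dict:
    """Aligned Z (NA = missing) and variant metadata as TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    z_path = out_dir / "zmatrix.tsv"
    v_path = out_dir / "variants.tsv"
    zmat.Z.to_csv(z_path, sep="\t", na_rep="NA", index_label="variant_id")
    zmat.variants.to_csv(v_path, sep="\t", index_label="variant_id")
    return {"zmatrix": z_path, "variants": v_path}


def write_nonneg_matrix(nn, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nn.X.to_csv(path, sep="\t", index_label="variant_id")
    return path


def read_nonneg_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant_id")


# -- cluster weights ---------------------------------------------------------


def write_cluster_definitions(defs: ClusterDefinitions, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    v_path = out_dir / "variant_weights.tsv"
    t_path = out_dir / "trait_weights.tsv"
    defs.variant_weights.to_csv(v_path, sep="\t", index=False)
    defs.trait_weights.to_csv(t_path, sep="\t", index=False)
    return {"variant_weights": v_path, "trait_weights": t_path}


def read_cluster_definitions(variant_weights_path, trait_weights_path=None, cutoff=0.84) -> ClusterDefinitions:
    vw = pd.read_csv(variant_weights_path, sep="\t")
    tw = (
        pd.read_csv(trait_weights_path, sep="\t")
        if trait_weights_path is not None and os.path.exists(str(trait_weights_path))
        else pd.DataFrame(columns=["cluster", "trait", "signed_weight"])
    )
    return ClusterDefinitions(variant_weights=vw, trait_weights=tw, cutoff=cutoff)


# -- LD reference ------------------------------------------------------------


def write_ld_reference(ld: LDReference, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    f_path = out_dir / "frequencies.tsv"
    r_path = out_dir / "ld_pairs.tsv"
    pd.Series({v: ld.frequency(v) for v in ld.variants}, name="frequency").to_csv(
        f_path, sep="\t", index_label="variant_id"
    )
    rows = []
    seen = set()
    for a in ld.variants:
        for b, r2 in ld.linked(a):
            if (b, a) not in seen:
                rows.append((a, b, r2))
                seen.add((a, b))
    pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"]).to_csv(
        r_path, sep="\t", index=False
    )
    return {"frequencies": f_path, "ld_pairs": r_path}


def read_ld_reference(freq_path, pairs_path=None) -> LDReference:
    freqs = pd.read_csv(freq_path, sep="\t", index_col="variant_id")["frequency"]
    pairs = []
    if pairs_path is not None and os.path.exists(str(pairs_path)):
        df = pd.read_csv(pairs_path, sep="\t")
        pairs = list(df.itertuples(index=False, name=None))
    return LDReference(frequencies=freqs.to_dict(), pairs=pairs)


# -- genotypes ---------------------------------------------------------------


def write_dosage_tsv(panel: GenotypePanel, path) -> Path:
    """Individuals x variants dosage matrix plus a sidecar allele table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(panel.dosages, index=panel.individuals, columns=panel.variants.index)
    frame.to_csv(path, sep="\t", na_rep="NA", index_label="individual_id")
    panel.variants.to_csv(path.with_suffix(".variants.tsv"), sep="\t", index_label="variant_id")
    return path


def read_dosage_tsv(path, variants_path=None) -> GenotypePanel:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="individual_id", na_values="NA")
    vpath = Path(variants_path) if variants_path else path.with_suffix(".variants.tsv")
    variants = pd.read_csv(vpath, sep="\t", index_col="variant_id")
    variants = variants.loc[frame.columns]
    return GenotypePanel.from_dosages(list(frame.index), variants, frame.to_numpy(dtype=float))


def write_vcf(panel: GenotypePanel, path) -> Path:
    """VCF v4.2 with a DS FORMAT field; REF = other allele, ALT = effect allele."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    variants = panel.variants
    keys = [
        (int(variants.iloc[i]["chromosome"]), int(variants.iloc[i]["position"]))
        for i in range(len(variants))
    ]
    order = sorted(range(len(variants)), key=keys.__getitem__)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, panel.individuals)) + "\n")
        for i in order:
            row = variants.iloc[int(i)]
            vid = variants.index[int(i)]
            ds = panel.dosages[:, int(i)]
            fields = [
                str(int(row["chromosome"])),
                str(int(row["position"])),
                str(vid),
                str(row["other_allele"]),
                str(row["effect_allele"]),
                ".",
                "PASS",
                ".",
                "DS",
            ]
            fields += ["." if np.isnan(d) else f"{d:g}" for d in ds]
            fh.write("\t".join(fields) + "\n")
    return path


def read_vcf(path) -> GenotypePanel:
    """Read dosages from the DS field, falling back to summing GT alt alleles."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, cols = [], []
    for v in vcf:
        ds = v.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            d = np.array(
                [np.nan if -1 in g[:2] else float(g[0] + g[1]) for g in v.genotypes],
                dtype=float,
            )
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append(
            dict(
                variant_id=vid,
                chromosome=v.CHROM,
                position=v.POS,
                effect_allele=v.ALT[0] if v.ALT else "N",
                other_allele=v.REF,
            )
        )
        cols.append(d)
    variants = pd.DataFrame(rows).set_index("variant_id")
    dosages = np.column_stack(cols) if cols else np.empty((len(individuals), 0))
    return GenotypePanel.from_dosages(individuals, variants, dosages)


def read_genotypes(path) -> GenotypePanel:
    """Dispatch on extension: ``.vcf`` vs dosage TSV."""
    if str(path).endswith(".vcf"):
        return read_vcf(path)
    return read_dosage_tsv(path)


# -- scores, cutoffs, phenotypes, results ------------------------------------


def write_pps(pps: PPSTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pps.scores.to_csv(path, sep="\t", index_label="individual_id")
    return path


def read_pps(path) -> PPSTable:
    frame = pd.read_csv(path, sep="\t", index_col="individual_id")
    frame.index.name = None
    return PPSTable(scores=frame, n_variants={})


def write_cutoffs(cutoffs: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.Series(cutoffs, name="cutoff").to_csv(path, sep="\t", index_label="cluster")
    return path


def read_cutoffs(path) -> dict:
    return pd.read_csv(path, sep="\t", index_col="cluster")["cutoff"].to_dict()


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, sep="\t", index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_association_results(results, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
    return path


def read_association_results(source):
    from .assoc import AssociationResult

    if any(ch in str(source) for ch in "*?["):
        paths = sorted(_glob.glob(str(source)))
    else:
        paths = [source]
    results = []
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        for rec in df.to_dict("records"):
            rec["usable"] = bool(rec.get("usable", True))
            rec["reason"] = "" if pd.isna(rec.get("reason", "")) else str(rec.get("reason", ""))
            results.append(AssociationResult(**rec))
    return results
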