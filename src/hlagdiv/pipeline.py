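"""Config-driven orchestration of the full locus analysis.

``run_pipeline`` executes, in order: variant inventory; haplotype
inventories and frequency tables at four resolutions (full gene, coding
allele, protein allotype, 3'UTR); the allele <-> 3'UTR association table;
protein translation and the functional-residue report; sliding-window
diversity with optional empirical-null calibration and a per-feature
summary; the HWE screen; the dN/dS table; LD pairs, complete-LD groups and
the tag-SNP set; and SNP- and haplotype-level FST with classical MDS.  All
artifacts are TSV/JSON under one output directory, indexed by a JSON
manifest that records parameters and seeds; each stage is individually
invocable through the functions this module wraps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, dnds, ld, popstruct
from .cohort import (
    PhasedCohort,
    SampleManifest,
    load_catalog,
    read_fasta,
    read_phased_vcf,
    write_fasta,
)
from .genemodel import GeneModel, load_gene_model
from .haplotypes import (
    associate_allele_utr,
    extract_haplotypes,
    frequency_table,
    name_haplotypes,
    variant_inventory,
)
from .proteins import residue_report, splice_cds, translate_cds


class ConfigError(ValueError):
    """Invalid or incomplete analysis configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    vcf: str = ""
    reference_fasta: str = ""
    gene_model: str = ""
    manifest: str = ""
    catalogs: dict[str, str] = field(default_factory=dict)  # level -> FASTA
    background_vcf: str = ""  # optional, for the empirical null
    out_dir: str = "results"
    seed: int = 0
    maf_min: float = 0.01
    polymorphism_threshold: float = 0.01
    tag_r2: float = 0.95
    pair_min_count: int = 2
    min_individuals: int = 10
    window: int = 500
    step: int = 1
    null_n_windows: int = 10_000
    bootstrap_reps: int = 1000
    signal_peptide_len: int = 24
    novel_prefixes: dict[str, str] = field(
        default_factory=lambda: {
            "full": "NOVEL-H", "cds": "NOVEL-G", "protein": "NOVEL-P", "utr3": "NOVEL-U"
        }
    )

    def validate(self) -> None:
        for name in ("vcf", "reference_fasta", "gene_model", "manifest"):
            if not getattr(self, name):
                raise ConfigError(f"config missing required field {name!r}")
        for name, lo, hi in [
            ("maf_min", 0, 0.5),
            ("polymorphism_threshold", 0, 1),
            ("tag_r2", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if self.window < 1 or self.step < 1 or self.min_individuals < 1:
            raise ConfigError("window/step/min_individuals must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields {sorted(unknown)}")
        return cls(**d)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage; returns the report bundle (artifact paths, key
    frames, warnings).  A stage failure aborts with the stage name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"artifacts": {}, "warnings": [], "config": asdict(config)}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        bundle["artifacts"][name] = str(path)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    @stage("load")
    def _load():
        model = load_gene_model(config.gene_model)
        ref = next(iter(read_fasta(config.reference_fasta).values()))
        manifest = SampleManifest.read_tsv(config.manifest)
        cohort = read_phased_vcf(config.vcf, model.interval, manifest)
        bundle.update(model=model, reference=ref, cohort=cohort)

    model: GeneModel = bundle["model"]
    cohort: PhasedCohort = bundle["cohort"]
    reference: str = bundle["reference"]
    ref_offset = model.interval.start

    @stage("variant_inventory")
    def _inventory():
        total, poly, table = variant_inventory(
            cohort, None, config.polymorphism_threshold
        )
        save("variant_inventory", table)
        utr_total, utr_poly, _ = variant_inventory(
            cohort, model.features["utr3"], config.polymorphism_threshold
        )
        bundle["counts"] = {
            "variants": total,
            "polymorphisms": poly,
            "utr3_variants": utr_total,
            "utr3_polymorphisms": utr_poly,
        }

    @stage("haplotypes")
    def _haplotypes():
        catalogs = {
            lvl: load_catalog(path, lvl) for lvl, path in config.catalogs.items()
        }
        level_seqs = {
            "full": extract_haplotypes(cohort, reference, model.interval, ref_offset),
            "cds": splice_cds(cohort, reference, model, ref_offset),
            "utr3": extract_haplotypes(
                cohort, reference, model.features["utr3"], ref_offset
            ),
        }
        canonical_len = sum(
            ex.end - (model.atg_genomic if i == 0 else ex.start)
            for i, ex in enumerate(model.coding_exons)
        ) // 3 - 1
        prots = [
            translate_cds(s, config.signal_peptide_len, canonical_aa_len=canonical_len)
            for s in level_seqs["cds"]
        ]
        level_seqs["protein"] = [p.precursor for p in prots]
        names, inventories = {}, {}
        for lvl, seqs in level_seqs.items():
            nm, inv = name_haplotypes(
                seqs, catalogs.get(lvl), config.novel_prefixes[lvl]
            )
            names[lvl], inventories[lvl] = nm, inv
            write_fasta(
                {f"{h.name}_count={h.global_count}": h.sequence for h in inv},
                out / f"haplotypes_{lvl}.fasta",
            )
            bundle["artifacts"][f"haplotypes_{lvl}"] = str(out / f"haplotypes_{lvl}.fasta")
            for grouping in ("global", "region", "country", "population"):
                ft = frequency_table(
                    nm, cohort.manifest, cohort.samples, lvl, grouping,
                    config.min_individuals,
                )
                save(f"frequencies_{lvl}_{grouping}", ft)
        assoc = associate_allele_utr(
            names["cds"], names["utr3"], config.pair_min_count
        )
        save("allele_utr_association", assoc)
        bundle.update(names=names, inventories=inventories, proteins=prots)

    @stage("residue_report")
    def _residues():
        prots = bundle["proteins"]
        names = bundle["names"]["protein"]
        ref_prot = translate_cds(
            _reference_cds(model, reference, ref_offset), config.signal_peptide_len
        )
        seen = {}
        for nm, p in zip(names, prots):
            if nm not in seen:
                p.name = nm
                seen[nm] = residue_report(p, ref_prot)
        rows = []
        for nm, rep in sorted(seen.items()):
            row = {"allotype": nm, "truncated": rep["truncated"]}
            row.update(rep["motifs"])
            row["polymorphic_residues"] = ";".join(
                f"{r}{p}{a}" for p, r, a in rep["polymorphic_residues"]
            )
            rows.append(row)
        save("residue_report", pd.DataFrame(rows))

    @stage("diversity")
    def _diversity():
        tracks = diversity.sliding_windows(
            cohort, model.interval, config.window, config.step
        )
        save("window_tracks", tracks)
        save("feature_summary", diversity.feature_summary(cohort, model))
        if config.background_vcf:
            bg = read_phased_vcf(config.background_vcf)
            lo = int(bg.positions.min())
            hi = int(bg.positions.max()) + 1
            iv = type(model.interval)(bg.variants[0].contig, lo, hi)
            nulls = diversity.empirical_null(
                bg, iv, config.null_n_windows, config.window,
                np.random.default_rng(config.seed),
            )
            payload = {
                name: {"mean": nd.mean, "q99": nd.q99, "q999": nd.q999,
                       "n_windows": int(len(nd.values))}
                for name, nd in nulls.items()
            }
            payload["seed"] = config.seed
            payload["window"] = config.window
            (out / "null_distribution.json").write_text(json.dumps(payload, indent=1))
            bundle["artifacts"]["null_distribution"] = str(out / "null_distribution.json")
        hwe = diversity.hwe_screen(cohort, config.min_individuals)
        save("hwe_screen", hwe)

    @stage("dnds")
    def _dnds():
        table = dnds_table(
            _cds_by_name(bundle), model,
            reps=config.bootstrap_reps, seed=config.seed,
        )
        save("dnds", table)

    @stage("ld")
    def _ld():
        sites, prov = ld.ld_site_filter(cohort, config.maf_min)
        save("ld_site_filter", prov)
        if len(sites) >= 2:
            pairs = ld.pairwise_ld(cohort, sites)
            save("ld_pairs", pairs)
            groups = ld.complete_ld_groups(pairs, sites)
            (out / "complete_ld_groups.json").write_text(
                json.dumps(groups, indent=1)
            )
            bundle["artifacts"]["complete_ld_groups"] = str(out / "complete_ld_groups.json")
            positions = {int(s): int(cohort.variants[s].pos) for s in sites}
            tags = ld.greedy_tag_selection(pairs, sites, positions, config.tag_r2)
            if not tags.verify(pairs):
                raise RuntimeError("tag-set cover failed post-hoc verification")
            (out / "tag_set.json").write_text(
                json.dumps(
                    {"threshold": tags.threshold, "tags": tags.tags,
                     "cover": {str(k): v for k, v in tags.cover.items()},
                     "uncovered": tags.uncovered},
                    indent=1,
                )
            )
            bundle["artifacts"]["tag_set"] = str(out / "tag_set.json")
            bundle["ld"] = {"sites": sites, "pairs": pairs, "groups": groups, "tags": tags}
        else:
            bundle["warnings"].append("fewer than 2 LD-eligible sites; LD skipped")

    @stage("structure")
    def _structure():
        try:
            fst = popstruct.snp_fst_pairwise(cohort, config.min_individuals)
        except ValueError as exc:
            bundle["warnings"].append(f"SNP FST skipped: {exc}")
            return
        fst.to_frame().to_csv(out / "fst_snp.tsv", sep="\t")
        bundle["artifacts"]["fst_snp"] = str(out / "fst_snp.tsv")
        emb = popstruct.classical_mds(fst, k=2)
        save("mds_snp", emb.to_frame())
        ft = frequency_table(
            bundle["names"]["cds"], cohort.manifest, cohort.samples,
            "cds", "population", config.min_individuals,
        )
        hfst = popstruct.haplotype_fst_pairwise(ft, config.min_individuals)
        hfst.to_frame().to_csv(out / "fst_haplotype.tsv", sep="\t")
        bundle["artifacts"]["fst_haplotype"] = str(out / "fst_haplotype.tsv")
        save("mds_haplotype", popstruct.classical_mds(hfst, k=2).to_frame())
        bundle["fst"] = {"snp": fst, "haplotype": hfst, "mds": emb}

    manifest_payload = {
        "artifacts": bundle["artifacts"],
        "warnings": bundle["warnings"],
        "parameters": asdict(config),
        "seed": config.seed,
    }
    (out / "report_manifest.json").write_text(json.dumps(manifest_payload, indent=1))
    bundle["artifacts"]["report_manifest"] = str(out / "report_manifest.json")
    return bundle


def _reference_cds(model: GeneModel, reference: str, ref_offset: int) -> str:
    parts = []
    for i, ex in enumerate(model.coding_exons):
        start = model.atg_genomic if i == 0 else ex.start
        parts.append(reference[start - ref_offset : ex.end - ref_offset])
    return "".join(parts)


def _cds_by_name(bundle: dict) -> dict[str, str]:
    inv = bundle["inventories"]["cds"]
    return {h.name: h.sequence for h in inv}


def codon_regions(model: GeneModel) -> dict[str, tuple[int, int]]:
    """Codon index ranges (0-based, half-open) of each coding exon, the full
    CDS, and the classical pooled subsets; only codons fully inside an exon
    count toward it.  The stop codon is excluded everywhere."""
    bounds = []
    off = 0
    for i, ex in enumerate(model.coding_exons):
        start = model.atg_genomic if i == 0 else ex.start
        ln = ex.end - start
        bounds.append((off, off + ln))
        off += ln
    n_codons = off // 3 - 1  # drop stop
    regions = {}
    for i, (s, e) in enumerate(bounds, start=1):
        c0 = (s + 2) // 3
        c1 = min(e // 3, n_codons)
        if c1 > c0:
            regions[f"exon{i}"] = (c0, c1)
    regions["all_exons"] = (0, n_codons)
    if "exon2" in regions and "exon3" in regions:
        regions["exons_2_3"] = (regions["exon2"][0], regions["exon3"][1])
    if "exon2" in regions and "exon4" in regions:
        regions["exons_2_3_4"] = (regions["exon2"][0], regions["exon4"][1])
    return regions


def dnds_table(
    cds_seqs: dict[str, str],
    model: GeneModel,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region dN/dS Z-tests over the distinct full-length coding
    sequences (one copy each; frameshifted, length-shifted or
    internally-stopped sequences are excluded and counted)."""
    lengths = [len(s) for s in cds_seqs.values()]
    canonical = max(set(lengths), key=lengths.count)  # modal CDS length
    usable = []
    excluded = 0
    for name in sorted(cds_seqs):
        full = cds_seqs[name]
        if len(full) != canonical or canonical % 3:
            excluded += 1
            continue
        seq = full[:-3] if dnds._aa(full[-3:]) == "*" else full
        if any(dnds._aa(seq[i : i + 3]) == "*" for i in range(0, len(seq), 3)):
            excluded += 1
            continue
        usable.append(seq)
    rows = []
    rng = np.random.default_rng(seed)
    for region, (c0, c1) in codon_regions(model).items():
        subset = sorted({s[3 * c0 : 3 * c1] for s in usable})
        row = {
            "region": region,
            "n_sequences": len(subset),
            "n_codons": c1 - c0,
            "excluded_sequences": excluded,
        }
        if len(subset) < 2 or c1 - c0 < 10:
            row["note"] = "insufficient data"
            rows.append(row)
            continue
        for alt in ("neutral", "positive", "purifying"):
            res = dnds.codon_z_test(
                subset, alt, reps, np.random.default_rng(rng.integers(0, 2**31))
            )
            row[f"z_{alt}"] = res.z
            row[f"p_{alt}"] = res.p_value
            row["d_N"] = res.d_N
            row["d_S"] = res.d_S
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(bundle_or_dir: dict | str | Path) -> str:
    """Human-readable summary; every number is recomputed from the artifact
    files, never taken from cached stage state."""
    if isinstance(bundle_or_dir, dict):
        art = bundle_or_dir["artifacts"]
    else:
        man = json.loads((Path(bundle_or_dir) / "report_manifest.json").read_text())
        art = man["artifacts"]
    lines = []
    inv = pd.read_csv(art["variant_inventory"], sep="\t")
    lines.append(
        f"{len(inv)} variants ({int(inv['polymorphic'].sum())} polymorphisms "
        "above the frequency threshold)"
    )
    level_words = {
        "full": "full-length haplotypes",
        "cds": "coding alleles",
        "protein": "protein allotypes",
        "utr3": "3'UTR haplotypes",
    }
    for lvl, word in level_words.items():
        ft = pd.read_csv(art[f"frequencies_{lvl}_global"], sep="\t")
        lines.append(f"{ft['name'].nunique()} {word}")
        top = ft.sort_values(["frequency", "name"], ascending=[False, True]).head(5)
        for _, r in top.iterrows():
            lines.append(f"    {r['name']}: {r['frequency']:.4f} ({r['count']} copies)")
    return "\n".join(lines)
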