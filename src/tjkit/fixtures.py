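"""Deterministic toy annotation sources for tests and demos.

Builds a miniature variant-annotation universe with a known answer key:

* a dbSNP-like catalog (rsID-keyed variants), built from a tab-delimited
  source table through the column-config path;
* a 1000-Genomes-like catalog carrying ``INFO.EUR_AF`` allele frequencies,
  built from a generated VCF through the VCF converter;
* a gene-feature catalog built from a generated BED file;
* the rsID input list and a ground-truth table stating, per rsID, the
  expected identifier-lookup hit, same-variant hit and frequency value.

A configurable fraction of dbSNP variants is mirrored in the frequency
catalog with the same landmark/position/ref/alt (these are the same-variant
matches); the rest get either no frequency entry or a deliberate near-miss
decoy at the same position with a different reference allele or disjoint
alternates.  Same seed, same spec => byte-identical files (compared on
decompressed content).

The generator emulates only the fields the annotation pipeline touches; it
does not attempt real dbSNP/1000G schema richness, realistic allele
frequency spectra, or non-SNV complexity beyond literal multi-base alleles.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .catalog import Catalog, ColumnConfig, build_catalog, compress_and_index, sort_catalog
from .formats import bed_to_tjson, vcf_to_tjson
from .tjson import TjsonRecord, extract_golden, is_json_cell

DBSNP_CONFIG = "\n".join(
    [
        "# dbSNP-like source: CHROM START END ID REF ALTS",
        "1\tCHROM\tlandmark",
        "2\tSTART\tstart",
        "3\tEND\tend",
        "4\tID\tid",
        "5\tREF\tref_allele",
        "6\tALTS\talt_alleles\tlist\t,",
    ]
)

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    """Parameters of the generated annotation universe."""

    seed: int = 0
    n_variants: int = 50
    n_genes: int = 10
    landmarks: tuple[str, ...] = ("chr1", "chr2")
    alphabet: str = _BASES
    fraction_multi_allelic: float = 0.2
    fraction_indels: float = 0.1
    overlap_fraction: float = 0.6  # of variants mirrored in the frequency catalog
    decoy_fraction: float = 0.5  # of unmatched variants given a near-miss entry
    frequency_field: str = "INFO.EUR_AF"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not self.landmarks:
            raise ValueError("landmark list is empty")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")


@dataclass
class Variant:
    landmark: str
    pos: int
    rsid: str
    ref: str
    alts: tuple[str, ...]
    matched: bool = False
    decoy: Optional[str] = None  # "ref" or "alt" near-miss kind
    eur_af: Optional[str] = None


@dataclass
class FixtureSet:
    """Paths of one generated fixture plus its in-memory answer key."""

    spec: FixtureSpec
    outdir: str
    dbsnp: Catalog
    kgenomes: Catalog
    genes: Catalog
    rsid_path: str
    truth_path: str
    variants: list[Variant] = field(default_factory=list)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def n_matched(self) -> int:
        return sum(v.matched for v in self.variants)

    def truth_pairs(self) -> list[tuple[str, str]]:
        """Expected (rsID, frequency-or-'.') pairs of the annotation pipeline."""
        return [(v.rsid, v.eur_af if v.matched else ".") for v in self.variants]


def _draw_alleles(rng: random.Random, spec: FixtureSpec) -> tuple[str, tuple[str, ...]]:
    bases = spec.alphabet
    if rng.random() < spec.fraction_indels:
        ref = "".join(rng.choice(bases) for _ in range(rng.randint(2, 4)))
        alts = (ref[0],)  # a literal deletion, no normalization
    else:
        ref = rng.choice(bases)
        others = [b for b in bases if b != ref]
        k = 2 if rng.random() < spec.fraction_multi_allelic and len(others) > 1 else 1
        alts = tuple(rng.sample(others, k))
    return ref, alts


def _plan(spec: FixtureSpec) -> list[Variant]:
    rng = random.Random(spec.seed)
    n = spec.n_variants
    positions = rng.sample(range(1, 10_000_000), n)
    variants: list[Variant] = []
    for i, pos in enumerate(positions):
        ref, alts = _draw_alleles(rng, spec)
        variants.append(
            Variant(
                landmark=spec.landmarks[i % len(spec.landmarks)],
                pos=pos,
                rsid=f"rs{1000 + i}",
                ref=ref,
                alts=alts,
            )
        )
    n_matched = round(spec.overlap_fraction * n)
    for idx in rng.sample(range(n), n_matched):
        variants[idx].matched = True
    for v in variants:
        if v.matched:
            v.eur_af = f"{rng.random():.4f}"
        elif rng.random() < spec.decoy_fraction:
            v.decoy = rng.choice(("ref", "alt"))
    return variants


def _dbsnp_rows(variants: list[Variant]) -> Iterator[str]:
    for v in variants:
        end = v.pos + len(v.ref) - 1
        yield f"{v.landmark}\t{v.pos}\t{end}\t{v.rsid}\t{v.ref}\t{','.join(v.alts)}"


def _kgenomes_vcf(variants: list[Variant], rng: random.Random, alphabet: str) -> Iterator[str]:
    yield "##fileformat=VCFv4.2"
    yield '##INFO=<ID=EUR_AF,Number=1,Type=Float,Description="European allele frequency">'
    yield "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    for v in variants:
        if v.matched:
            ref, alts, af = v.ref, v.alts, v.eur_af
        elif v.decoy == "ref":
            # same position, different reference allele: must not match
            ref = next(b for b in alphabet if b != v.ref[0])
            alts, af = v.alts, f"{rng.random():.4f}"
        elif v.decoy == "alt":
            # same position and ref, disjoint alternate set: must not match
            pool = [b for b in alphabet if b != v.ref[0] and b not in v.alts]
            if not pool:
                continue
            ref, alts, af = v.ref, (rng.choice(pool),), f"{rng.random():.4f}"
        else:
            continue
        info = "EUR_AF=" + af
        yield f"{v.landmark}\t{v.pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t{info}"


def _gene_bed(spec: FixtureSpec, rng: random.Random) -> Iterator[str]:
    for i in range(spec.n_genes):
        chrom = spec.landmarks[i % len(spec.landmarks)]
        start0 = rng.randrange(0, 9_990_000)
        length = rng.randint(500, 5000)
        strand = rng.choice("+-")
        yield f"{chrom}\t{start0}\t{start0 + length}\tg{i + 1}\t0\t{strand}"


def tjson_to_catalog_lines(stream) -> Iterator[str]:
    """Turn TJSON lines into 4-column catalog lines via their golden keys."""
    for line in stream:
        if line.startswith("#"):
            continue
        record = TjsonRecord.parse(line)
        for cell in reversed(record.columns):
            if is_json_cell(cell):
                g = extract_golden(cell)
                min_bp = g.min_bp if g.min_bp is not None else 0
                max_bp = g.max_bp if g.max_bp is not None else 0
                yield f"{g.landmark}\t{min_bp}\t{max_bp}\t{cell}"
                break


def generate_fixture(spec: FixtureSpec, outdir: "str | os.PathLike") -> FixtureSet:
    """Generate the full fixture set under *outdir*.

    Catalogs are built through the regular catalog-construction path
    (create -> sort -> BGZF compress -> Tabix index), so generating a
    fixture also exercises it.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    variants = _plan(spec)
    rng = random.Random(spec.seed + 1)  # decoy/bed draws, separate stream

    config = ColumnConfig.parse(DBSNP_CONFIG)
    dbsnp = build_catalog(_dbsnp_rows(variants), config, os.path.join(outdir, "dbSNP"))
    dbsnp.id_index("_id")

    kg_lines = tjson_to_catalog_lines(
        vcf_to_tjson(_kgenomes_vcf(variants, rng, spec.alphabet))
    )
    kgenomes = compress_and_index(
        sort_catalog(kg_lines), os.path.join(outdir, "KGenomes")
    )

    gene_lines = tjson_to_catalog_lines(bed_to_tjson(_gene_bed(spec, rng)))
    genes = compress_and_index(sort_catalog(gene_lines), os.path.join(outdir, "genes"))

    rsid_path = os.path.join(outdir, "rsIDs.txt")
    with open(rsid_path, "w", encoding="utf-8") as fh:
        for v in variants:
            fh.write(v.rsid + "\n")

    truth_path = os.path.join(outdir, "truth.tsv")
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("#rsid\tlookup_hit\tsame_variant_hit\teur_af\n")
        for v in variants:
            fh.write(
                f"{v.rsid}\t1\t{int(v.matched)}\t{v.eur_af if v.matched else '.'}\n"
            )

    return FixtureSet(
        spec=spec,
        outdir=outdir,
        dbsnp=dbsnp,
        kgenomes=kgenomes,
        genes=genes,
        rsid_path=rsid_path,
        truth_path=truth_path,
        variants=variants,
    )


def recompute_truth_by_scan(fixture: FixtureSet) -> list[tuple[str, str]]:
    """Re-derive the (rsID, frequency) answer key by brute-force scans.

    Ignores the generator's bookkeeping entirely: looks each rsID up by
    linear scan of the dbSNP-like catalog, applies the same-variant rule by
    linear scan of the frequency catalog, and drills the frequency out of
    the matching payload.  Used to cross-check the constructed ground
    truth.
    """
    from .tjson import drill

    db_entries = list(fixture.dbsnp.iter_entries())
    kg_entries = list(fixture.kgenomes.iter_entries())
    with open(fixture.rsid_path, encoding="utf-8") as fh:
        rsids = [line.strip() for line in fh if line.strip()]
    pairs: list[tuple[str, str]] = []
    for rsid in rsids:
        hits = [e for e in db_entries if drill(e.json_text, "_id") == rsid]
        freq = "."
        for hit in hits:
            g = extract_golden(hit.json_text)
            for kg in kg_entries:
                kgold = extract_golden(kg.json_text)
                if (
                    kgold.landmark == g.landmark
                    and kgold.min_bp == g.min_bp
                    and kgold.ref_allele == g.ref_allele
                    and kgold.alt_alleles
                    and g.alt_alleles
                    and not set(kgold.alt_alleles).isdisjoint(g.alt_alleles)
                ):
                    freq = drill(kg.json_text, fixture.spec.frequency_field)
        pairs.append((rsid, freq))
    return pairs
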