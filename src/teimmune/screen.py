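"""Candidate-adaptive TE screening.

The screen starts from the full reference TE annotation and removes, in
order: INE-1 elements (an ancient family fixed in D. melanogaster),
insertions flanked by simple repeats / nested in other TEs / inside
segmental duplications (presence/absence cannot be called reliably for
them), and insertions in genomic regions of zero recombination (where
selection is inefficient and linkage confounds adaptive inference).
Population frequencies are then estimated from per-strain
presence/absence calls, fixed insertions are set aside, and TEs at high
frequency in at least one population are carried forward and annotated
with their nearby genes.

Coordinates are 1-based inclusive internally; BED export is 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TECatalog", "RecombinationMap", "GenotypeMatrix",
    "PopulationFrequencyTable", "CascadeReport", "GeneRecord",
    "read_genes_gff3",
    "apply_exclusion_cascade", "population_frequency", "select_candidates",
    "screen_nonreference", "assign_genes", "assign_genes_all",
    "intersect_immune",
]

TE_CLASSES = ("DNA", "LTR", "non-LTR")

_CATALOG_COLUMNS = [
    "id", "family", "te_class", "chrom", "start", "end", "length_bp",
    "completeness", "is_reference", "is_ine1", "repeat_flanked_or_nested",
]


class TECatalog:
    """A table of TE insertions with screening flags.

    Thin wrapper around a DataFrame with one row per insertion; rows carry
    identity (id, family, class), 1-based inclusive coordinates and the
    boolean exclusion flags consumed by the cascade.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate TE ids: {dupes[:5]}")
        if len(df) and not (df["start"] <= df["end"]).all():
            raise ValueError("TE start must be <= end")
        if len(df) and not (df["length_bp"] >= 1).all():
            raise ValueError("TE length_bp must be >= 1")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "TECatalog":
        return TECatalog(self.df.loc[mask].reset_index(drop=True))

    # --- I/O -----------------------------------------------------------
    def to_bed(self, path) -> None:
        """Write coordinates as BED (0-based half-open) with the id as name."""
        bed = pd.DataFrame({
            "chrom": self.df["chrom"],
            "start": self.df["start"] - 1,
            "end": self.df["end"],
            "name": self.df["id"],
        })
        bed.to_csv(path, sep="\t", header=False, index=False)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TECatalog":
        return cls(pd.read_csv(path, sep="\t"))


class RecombinationMap:
    """Recombination-rate intervals (cM/Mb) for one map dialect.

    Intervals are half-open [start, end) internally, non-overlapping and
    sorted within each chromosome.
    """

    def __init__(self, intervals: pd.DataFrame, dialect: str = "map_A"):
        req = {"chrom", "start", "end", "rate"}
        if not req.issubset(intervals.columns):
            raise ValueError(f"map requires columns {sorted(req)}")
        if len(intervals) and (intervals["rate"] < 0).any():
            raise ValueError("recombination rates must be >= 0")
        self.dialect = dialect
        self.intervals = (intervals.sort_values(["chrom", "start"])
                          .reset_index(drop=True))
        self._by_chrom = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(),
                    sub["rate"].to_numpy())
            for chrom, sub in self.intervals.groupby("chrom")
        }

    @property
    def chromosomes(self) -> set:
        return set(self._by_chrom)

    def rate_at(self, chrom: str, pos: int) -> float | None:
        """Rate at a 1-based position; None if the position is uncovered."""
        if chrom not in self._by_chrom:
            return None
        starts, ends, rates = self._by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i < 0 or pos >= ends[i]:
            return None
        return float(rates[i])

    def to_tsv(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, dialect: str = "map_A") -> "RecombinationMap":
        return cls(pd.read_csv(path, sep="\t"), dialect=dialect)


@dataclass
class CascadeReport:
    """Per-step accounting of the exclusion cascade."""

    input_count: int
    steps: list = field(default_factory=list)  # (name, excluded, remaining)

    def add(self, name: str, excluded: int, remaining: int) -> None:
        self.steps.append((name, int(excluded), int(remaining)))

    @property
    def retained(self) -> int:
        return self.steps[-1][2] if self.steps else self.input_count

    def validate(self) -> None:
        remaining = self.input_count
        for name, excluded, after in self.steps:
            if after != remaining - excluded:
                raise AssertionError(f"cascade counts inconsistent at {name}")
            remaining = after

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "excluded", "remaining"])


def apply_exclusion_cascade(catalog: TECatalog,
                            maps: Sequence[RecombinationMap],
                            zero_recomb_rule: str = "either",
                            ) -> tuple[TECatalog, CascadeReport]:
    """Run the sequential exclusion cascade.

    Order: INE-1 -> repeat-flanked/nested -> zero recombination. Each step
    counts only TEs that survived the previous steps, so the per-step
    counts reconcile by subtraction. A TE is in a zero-recombination
    region when the rate at its midpoint is 0 in either map
    (``zero_recomb_rule="either"``, default) or in both
    (``"both"``). Positions uncovered by a map are treated as rate 0 in
    that map and logged.
    """
    if zero_recomb_rule not in ("either", "both"):
        raise ValueError("zero_recomb_rule must be 'either' or 'both'")
    if len(maps) != 2:
        raise ValueError("expected exactly two recombination maps")

    df = catalog.df
    report = CascadeReport(input_count=len(df))

    covered = set.union(set(), *(m.chromosomes for m in maps))
    bad = sorted(set(df["chrom"]) - covered)
    if bad:
        offenders = df.loc[df["chrom"].isin(bad), "id"].tolist()
        raise ValueError(
            f"TEs on chromosomes absent from both maps: {bad}; "
            f"offending ids (first 10): {offenders[:10]}")

    keep = ~df["is_ine1"].astype(bool)
    report.add("INE-1", int((~keep).sum()), int(keep.sum()))

    keep2 = keep & ~df["repeat_flanked_or_nested"].astype(bool)
    report.add("repeat-flanked/nested", int((keep & ~keep2).sum()),
               int(keep2.sum()))

    mid = ((df["start"] + df["end"]) // 2).to_numpy()
    n_uncovered = 0

    def zero_in(m: RecombinationMap, chrom: str, pos: int) -> bool:
        nonlocal n_uncovered
        r = m.rate_at(chrom, int(pos))
        if r is None:
            n_uncovered += 1
            return True
        return r == 0.0

    chroms = df["chrom"].to_numpy()
    flags = np.zeros(len(df), dtype=bool)
    for i in np.flatnonzero(keep2.to_numpy()):
        za = zero_in(maps[0], chroms[i], mid[i])
        zb = zero_in(maps[1], chroms[i], mid[i])
        flags[i] = (za or zb) if zero_recomb_rule == "either" else (za and zb)
    if n_uncovered:
        logger.warning("%d TE midpoints uncovered by a map; treated as rate 0",
                       n_uncovered)

    keep3 = keep2 & ~pd.Series(flags, index=df.index)
    report.add("zero-recombination", int((keep2 & ~keep3).sum()),
               int(keep3.sum()))
    report.validate()
    return catalog.subset(keep3), report


class GenotypeMatrix:
    """Per-strain TE presence/absence calls with a strain->population map.

    ``calls`` is a DataFrame indexed by TE id with one column per strain;
    values are 'P' (present), 'A' (absent) or '-' (missing).
    """

    PRESENT, ABSENT, MISSING = "P", "A", "-"

    def __init__(self, calls: pd.DataFrame, strain_to_pop: dict[str, str]):
        unknown = set(calls.columns) - set(strain_to_pop)
        if unknown:
            raise ValueError(f"strains without a population: {sorted(unknown)[:5]}")
        bad = set(np.unique(calls.to_numpy())) - {"P", "A", "-"}
        if bad:
            raise ValueError(f"invalid call values: {sorted(bad)}")
        self.calls = calls
        self.strain_to_pop = dict(strain_to_pop)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.strain_to_pop.values():
            seen.setdefault(pop, None)
        return list(seen)

    def to_tsv(self, path, pops_path=None) -> None:
        self.calls.to_csv(path, sep="\t", index_label="te")
        if pops_path is not None:
            pd.Series(self.strain_to_pop, name="population").rename_axis(
                "strain").to_csv(pops_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, pops_path) -> "GenotypeMatrix":
        calls = pd.read_csv(path, sep="\t", index_col="te")
        pops = pd.read_csv(pops_path, sep="\t", index_col="strain")["population"]
        return cls(calls, pops.to_dict())


class PopulationFrequencyTable:
    """Estimated TE frequency per population plus the call denominator.

    ``freq`` is NaN where no strain was called (all-missing); such cells
    are reported as undefined, never as zero.
    """

    def __init__(self, freq: pd.DataFrame, n_called: pd.DataFrame):
        if not freq.index.equals(n_called.index) or \
           not freq.columns.equals(n_called.columns):
            raise ValueError("freq and n_called must be aligned")
        self.freq = freq
        self.n_called = n_called

    @property
    def undefined(self) -> pd.DataFrame:
        return self.n_called == 0

    def to_tsv(self, path) -> None:
        self.freq.to_csv(path, sep="\t", index_label="te", na_rep="NA")


def population_frequency(genotypes: GenotypeMatrix) -> PopulationFrequencyTable:
    """Estimate per-population TE frequencies as present / called.

    Missing calls are excluded from the denominator; an all-missing
    (TE, population) cell has an undefined (NaN) frequency.
    """
    pops = genotypes.populations
    calls = genotypes.calls
    freq = pd.DataFrame(index=calls.index, columns=pops, dtype=float)
    n_called = pd.DataFrame(0, index=calls.index, columns=pops, dtype=int)
    for pop in pops:
        strains = [s for s in calls.columns
                   if genotypes.strain_to_pop[s] == pop]
        sub = calls[strains]
        present = (sub == GenotypeMatrix.PRESENT).sum(axis=1)
        absent = (sub == GenotypeMatrix.ABSENT).sum(axis=1)
        called = present + absent
        n_called[pop] = called
        with np.errstate(invalid="ignore"):
            freq[pop] = np.where(called > 0, present / called.replace(0, 1),
                                 np.nan)
    n_undef = int((n_called == 0).any(axis=1).sum())
    if n_undef:
        logger.warning("%d TEs have an undefined frequency in >=1 population",
                       n_undef)
    return PopulationFrequencyTable(freq, n_called)


def select_candidates(freqs: PopulationFrequencyTable,
                      threshold: float = 0.10) -> pd.DataFrame:
    """High-frequency, non-fixed candidate TEs.

    Keeps TEs with estimated frequency >= ``threshold`` in at least one
    population that are not fixed (frequency exactly 1) in every
    population where a frequency is defined. Fixed insertions are set
    aside because comparative experiments between flies with and without
    the insertion are impossible.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    f = freqs.freq
    defined = f.notna()
    any_defined = defined.any(axis=1)
    fixed = ((f == 1.0) | ~defined).all(axis=1) & any_defined
    high = (f >= threshold).any(axis=1)
    keep = high & ~fixed & any_defined
    out = pd.DataFrame({
        "te": f.index[keep],
        "max_frequency": f.loc[keep].max(axis=1).to_numpy(),
        "populations_passing": [
            ",".join(f.columns[(f.loc[te] >= threshold).fillna(False)])
            for te in f.index[keep]
        ],
    }).reset_index(drop=True)
    return out


def screen_nonreference(presence_counts: pd.DataFrame,
                        min_strains: int = 15,
                        panel_size: int = 177,
                        threshold: float = 0.10) -> pd.DataFrame:
    """Screen de novo (non-reference) TE insertions from panel counts.

    ``presence_counts`` needs columns ``te``, ``count`` (strains carrying
    the insertion out of ``panel_size``) and ``verified`` (PCR-confirmed
    presence). TEs are retained when count >= ``min_strains``, the call
    was verified, and the implied frequency count/panel_size passes the
    candidate threshold.
    """
    df = presence_counts
    if (df["count"] > panel_size).any():
        bad = df.loc[df["count"] > panel_size, "te"].tolist()
        raise ValueError(f"counts exceed panel size for: {bad[:5]}")
    if (df["count"] < 0).any():
        raise ValueError("negative presence counts")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    keep = (df["count"] >= min_strains) & df["verified"].astype(bool)
    out = df.loc[keep, ["te", "count"]].copy()
    out["frequency"] = out["count"] / panel_size
    out = out[out["frequency"] >= threshold].reset_index(drop=True)
    return out


@dataclass
class GeneRecord:
    """A gene with transcript CDS structure and an immune-evidence flag.

    ``transcripts`` maps transcript id -> sorted list of (start, end) CDS
    intervals (1-based inclusive). ``evidence`` is a subset of
    {"expression", "survival", "pathway"} describing the literature
    support for an immune role; the curation itself is input data.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    immune_flag: bool = False
    evidence: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for tid, cds in self.transcripts.items():
            for s, e in cds:
                if not (self.start <= s <= e <= self.end):
                    raise ValueError(
                        f"CDS of {tid} outside gene span of {self.gene_id}")


def read_genes_gff3(path, immune_sidecar=None) -> list[GeneRecord]:
    """Read gene records from a GFF3-like annotation.

    ``gene`` features define spans; ``CDS`` features are attached to the
    transcript named by their ``Parent`` attribute (which must itself
    name the gene in its own ``Parent``). Immune flags come from an
    ``immune=1`` attribute on the gene line or from a sidecar TSV with
    columns ``gene_id``, ``immune_flag`` and optional ``evidence``
    (comma-separated classes).
    """
    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)

    def attrs(s: str) -> dict:
        return dict(kv.split("=", 1) for kv in s.split(";") if "=" in kv)

    sidecar = {}
    if immune_sidecar is not None:
        sc = pd.read_csv(immune_sidecar, sep="\t")
        for _, r in sc.iterrows():
            ev = r.get("evidence", "")
            sidecar[r["gene_id"]] = (
                bool(r["immune_flag"]),
                frozenset(str(ev).split(",")) if isinstance(ev, str) and ev
                else frozenset())

    genes: dict[str, dict] = {}
    tr_to_gene: dict[str, str] = {}
    for _, row in df.iterrows():
        a = attrs(row["attributes"])
        if row["type"] == "gene":
            gid = a["ID"]
            immune, evidence = sidecar.get(
                gid, (a.get("immune", "0") == "1",
                      frozenset(a["evidence"].split(","))
                      if a.get("evidence") else frozenset()))
            genes[gid] = {
                "gene_id": gid, "symbol": a.get("Name", gid),
                "chrom": row["chrom"], "start": int(row["start"]),
                "end": int(row["end"]), "strand": row["strand"],
                "transcripts": {}, "immune_flag": immune,
                "evidence": evidence,
            }
        elif row["type"] in ("mRNA", "transcript"):
            tr_to_gene[a["ID"]] = a["Parent"]
        elif row["type"] == "CDS":
            gid = tr_to_gene.get(a["Parent"])
            if gid in genes:
                genes[gid]["transcripts"].setdefault(a["Parent"], []).append(
                    (int(row["start"]), int(row["end"])))
    for g in genes.values():
        for cds in g["transcripts"].values():
            cds.sort()
    return [GeneRecord(**g) for g in genes.values()]


def _gap(te_start: int, te_end: int, g: GeneRecord) -> int:
    """Bases strictly between the TE span and the gene span (0 if overlap)."""
    if te_end < g.start:
        return g.start - te_end - 1
    if g.end < te_start:
        return te_start - g.end - 1
    return 0


def _relation(te_start: int, te_end: int, g: GeneRecord) -> str:
    """Strand-aware relation of the TE to the gene."""
    gap = _gap(te_start, te_end, g)
    if gap > 0 or (te_end < g.start or g.end < te_start):
        upstream = te_end < g.start if g.strand == "+" else te_start > g.end
        return "5'" if upstream else "3'"
    # overlapping: classify from transcript structure
    cds_all = [iv for cds in g.transcripts.values() for iv in cds]
    if any(not (te_end < s or e < te_start) for s, e in cds_all):
        return "exon"
    if cds_all:
        cds_lo = min(s for s, _ in cds_all)
        cds_hi = max(e for _, e in cds_all)
        if te_end < cds_lo or te_start > cds_hi:
            return "UTR"
    return "intron"


def assign_genes(te_chrom: str, te_start: int, te_end: int,
                 genes: Iterable[GeneRecord],
                 window_bp: int = 1000) -> list[dict]:
    """Genes associated with one TE insertion.

    Returns every gene whose gap to the TE is < ``window_bp`` (gap 0 for
    overlap). If none qualifies, the nearest gene is returned instead;
    equidistant nearest genes are all kept. Each association records the
    gap in bp and a strand-aware relation (5'/3' for non-overlapping TEs;
    exon/UTR/intron when the TE lies inside the gene span).
    """
    same_chrom = [g for g in genes if g.chrom == te_chrom]
    if not same_chrom:
        logger.warning("no genes on chromosome %s for TE at %d-%d",
                       te_chrom, te_start, te_end)
        return []
    gaps = [(_gap(te_start, te_end, g), g) for g in same_chrom]
    within = [(d, g) for d, g in gaps if d < window_bp]
    if not within:
        dmin = min(d for d, _ in gaps)
        within = [(d, g) for d, g in gaps if d == dmin]
    return [{
        "gene_id": g.gene_id,
        "symbol": g.symbol,
        "gap_bp": d,
        "relation": _relation(te_start, te_end, g),
        "immune_flag": g.immune_flag,
        "evidence": ",".join(sorted(g.evidence)),
    } for d, g in sorted(within, key=lambda t: (t[0], t[1].gene_id))]


def assign_genes_all(catalog: TECatalog, genes: Iterable[GeneRecord],
                     window_bp: int = 1000) -> pd.DataFrame:
    """Gene associations for every TE in a catalog, as a tidy table."""
    genes = list(genes)
    rows = []
    for _, te in catalog.df.iterrows():
        for assoc in assign_genes(te["chrom"], int(te["start"]),
                                  int(te["end"]), genes, window_bp):
            rows.append({"te": te["id"], **assoc})
    return pd.DataFrame(rows, columns=["te", "gene_id", "symbol", "gap_bp",
                                       "relation", "immune_flag", "evidence"])


def intersect_immune(candidates: pd.DataFrame,
                     associations: pd.DataFrame) -> pd.DataFrame:
    """Restrict candidates to TEs with >=1 associated immune gene.

    ``candidates`` must have a ``te`` column (e.g. from
    :func:`select_candidates`); ``associations`` is the output of
    :func:`assign_genes_all`. All genes of a retained TE are listed,
    immune or not, so a TE inserted between two genes keeps both.
    """
    if associations.empty or candidates.empty:
        return associations.iloc[0:0]
    cand = associations[associations["te"].isin(set(candidates["te"]))]
    immune_tes = set(cand.loc[cand["immune_flag"].astype(bool), "te"])
    return cand[cand["te"].isin(immune_tes)].reset_index(drop=True)
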