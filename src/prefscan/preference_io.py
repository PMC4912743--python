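"""Preference tables, alignment conversion and the tolerance metric k*.

Two input routes produce the same in-memory table:

* deep mutational scanning data, already expressed as per-site amino acid
  preferences (any metric that increases with the probability of observing
  each amino acid), parsed from a tab-delimited matrix;
* a gapped protein alignment, converted column-by-column to "statistical
  free energies"  ddG(i, j) = -log10(P(i, j) / P(wt, j))  where P are
  pseudocounted amino acid frequencies relative to the reference sequence's
  residue at position j.

The tolerance to substitution k* of a site is the base-2 exponential of the
Shannon entropy of the site's amino acid frequencies (the perplexity, or
effective number of amino acids): 1 when a single amino acid is tolerated,
20 when all are equally tolerated.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .descriptors import AMINO_ACIDS

_AA_SET = set(AMINO_ACIDS)
_GAP_CHARS = {"-", "."}


@dataclass
class SiteRecord:
    """One residue's amino acid distribution.

    ``preferences`` holds either the raw preference metric ("higher = more
    preferred") or ddG values ("lower = more preferred", 0 for the wild
    type), depending on the owning table's ``metric_kind``.
    """

    wt_aa: str
    residue_number: int
    preferences: dict[str, float]
    kstar: float | None = None
    kstar_source: str | None = None  # "user-provided" or "computed"
    extra: float | None = None
    low_coverage: bool = False

    def pref_array(self) -> np.ndarray:
        return np.array([self.preferences[a] for a in AMINO_ACIDS], dtype=float)


@dataclass
class PreferenceTable:
    sites: list[SiteRecord]
    metric_kind: str = "preference"  # "preference" or "ddg"
    source: str = ""

    def __post_init__(self) -> None:
        if self.metric_kind not in ("preference", "ddg"):
            raise ValueError(f"metric_kind must be 'preference' or 'ddg', "
                             f"got {self.metric_kind!r}")
        nums = [s.residue_number for s in self.sites]
        if len(nums) != len(set(nums)):
            dup = sorted({n for n in nums if nums.count(n) > 1})
            raise ValueError(f"duplicate residue number(s): {dup}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


@dataclass
class AlignmentProfile:
    """Per-query-position amino acid counts extracted from an alignment."""

    counts: list[dict[str, int]]
    gap_counts: list[int]
    excluded_counts: list[int]
    query_aa: list[str]
    residue_numbers: list[int]
    n_sequences: int


# ---------------------------------------------------------------------------
# Tab-delimited preference matrix


def parse_preference_table(text: str, metric_kind: str = "preference",
                           source: str = "") -> PreferenceTable:
    """Parse the tab-delimited preference matrix.

    Each data row carries: reference amino acid (1-letter), residue number,
    20 preference values, then optionally k* (column 23) and one free extra
    column (column 24).  A header row naming the 20 amino acid columns is
    accepted and fixes their order; without it the order is alphabetical by
    1-letter code.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty preference table")

    aa_order = list(AMINO_ACIDS)
    start = 0
    first = lines[0].split("\t")
    if len(first) >= 22 and not _is_number(first[2]):
        cols = [c.strip() for c in first[2:22]]
        if sorted(cols) != sorted(AMINO_ACIDS):
            bad = sorted(set(cols) ^ _AA_SET)
            raise ValueError(f"header row 1: amino acid columns must name each "
                             f"canonical amino acid once (problem: {bad})")
        aa_order = cols
        start = 1

    sites: list[SiteRecord] = []
    seen_nums: set[int] = set()
    for idx, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) not in (22, 23, 24):
            raise ValueError(f"row {idx}: expected 22, 23 or 24 tab-delimited "
                             f"fields, got {len(fields)}")
        wt = fields[0].strip().upper()
        if wt not in _AA_SET:
            raise ValueError(f"row {idx}: unknown amino acid code {fields[0]!r}")
        try:
            num = int(fields[1])
        except ValueError:
            raise ValueError(f"row {idx}: residue number {fields[1]!r} is not "
                             "an integer") from None
        if num in seen_nums:
            raise ValueError(f"row {idx}: duplicate residue number {num}")
        seen_nums.add(num)
        prefs: dict[str, float] = {}
        for aa, cell in zip(aa_order, fields[2:22]):
            try:
                prefs[aa] = float(cell)
            except ValueError:
                raise ValueError(f"row {idx}: non-numeric preference {cell!r} "
                                 f"for amino acid {aa}") from None
            if not math.isfinite(prefs[aa]):
                raise ValueError(f"row {idx}: non-finite preference for {aa}")
        kstar = kstar_src = None
        if len(fields) >= 23 and fields[22].strip():
            kstar = float(fields[22])
            kstar_src = "user-provided"
            if not 1.0 <= kstar <= 20.0:
                raise ValueError(f"row {idx}: k* = {kstar} outside [1, 20]")
        extra = float(fields[23]) if len(fields) == 24 and fields[23].strip() else None
        sites.append(SiteRecord(wt, num, prefs, kstar, kstar_src, extra))
    return PreferenceTable(sites=sites, metric_kind=metric_kind, source=source)


def write_preference_table(table: PreferenceTable, header: bool = True) -> str:
    """Serialise a table in the same tab-delimited dialect (round-trippable)."""
    out: list[str] = []
    if header:
        out.append("\t".join(["wt", "residue"] + list(AMINO_ACIDS) + ["kstar"]))
    for s in table.sites:
        cells = [s.wt_aa, str(s.residue_number)]
        cells += [repr(s.preferences[a]) for a in AMINO_ACIDS]
        cells.append("" if s.kstar is None else repr(s.kstar))
        out.append("\t".join(cells))
    return "\n".join(out) + "\n"


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Alignment -> ddG


def profile_alignment(records: list, query_id: str) -> AlignmentProfile:
    """Count amino acids per query position from gapped, equal-length records.

    Non-canonical letters (B, Z, X, U, O, ...) and gaps are excluded from the
    counts but tallied.  The query row defines the reference amino acid at
    each position; it is not itself counted as an observation.
    """
    if not records:
        raise ValueError("empty alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    query = next((r for r in records if r.id == query_id), None)
    if query is None:
        raise ValueError(f"query id {query_id!r} not found in alignment")
    others = [str(r.seq).upper() for r in records if r is not query]
    qseq = str(query.seq).upper()

    counts, gaps, excluded, q_aas, numbers = [], [], [], [], []
    resnum = 0
    for col, q_aa in enumerate(qseq):
        if q_aa in _GAP_CHARS:
            continue
        if q_aa not in _AA_SET:
            continue  # non-canonical query residue: no reference, skip column
        resnum += 1
        col_counts = {a: 0 for a in AMINO_ACIDS}
        n_gap = n_excl = 0
        for seq in others:
            ch = seq[col]
            if ch in _GAP_CHARS:
                n_gap += 1
            elif ch in _AA_SET:
                col_counts[ch] += 1
            else:
                n_excl += 1
        counts.append(col_counts)
        gaps.append(n_gap)
        excluded.append(n_excl)
        q_aas.append(q_aa)
        numbers.append(resnum)
    return AlignmentProfile(counts, gaps, excluded, q_aas, numbers,
                            n_sequences=len(others))


def alignment_to_ddg(alignment, query_id: str, pseudocount: float = 1.0,
                     residue_offset: int = 0) -> PreferenceTable:
    """Convert a gapped alignment into a ddG preference table.

    ``alignment`` is a path / handle of an aligned FASTA file, or an iterable
    of SeqRecord objects.  Per non-gap query position j, frequencies are
    P(i, j) = (count_i + pseudocount) / (total + 20 * pseudocount) over the
    non-query rows, and ddG(i, j) = -log10(P(i, j) / P(wt, j)), so the
    reference amino acid sits at exactly 0.  Residues are numbered by
    1-based ungapped query coordinate plus ``residue_offset``.  k* is filled
    from the same frequencies.  Columns where every non-query row is a gap
    are still emitted (the pseudocounts make them uniform) but flagged
    low-coverage.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    records = _as_records(alignment)
    profile = profile_alignment(records, query_id)

    sites: list[SiteRecord] = []
    for col_counts, n_gap, wt, num in zip(profile.counts, profile.gap_counts,
                                          profile.query_aa,
                                          profile.residue_numbers):
        total = sum(col_counts.values())
        denom = total + 20.0 * pseudocount
        p = {a: (col_counts[a] + pseudocount) / denom for a in AMINO_ACIDS}
        p_wt = p[wt]
        ddg = {a: -math.log10(p[a] / p_wt) for a in AMINO_ACIDS}
        ddg[wt] = 0.0
        rec = SiteRecord(wt, num + residue_offset, ddg,
                         low_coverage=(total == 0))
        rec.kstar = compute_kstar(rec, "ddg")
        rec.kstar_source = "computed"
        sites.append(rec)
    return PreferenceTable(sites=sites, metric_kind="ddg",
                           source=f"alignment:{query_id}")


def _as_records(alignment) -> list:
    if isinstance(alignment, (str, io.IOBase)):
        return list(SeqIO.parse(alignment, "fasta"))
    records = list(alignment)
    if records and isinstance(records[0], str):
        return list(SeqIO.parse(io.StringIO("\n".join(records)), "fasta"))
    return records


# ---------------------------------------------------------------------------
# Tolerance to substitution


def compute_kstar(site: SiteRecord, metric_kind: str) -> float:
    """Effective number of amino acids tolerated at a site (range [1, 20]).

    For ddG input, probabilities are recovered as P(i) = 10^(-ddG(i)) so the
    wild type sits at P = 1, then normalised to frequencies; for direct
    preferences the (non-negative) values are normalised as given.  The
    result is 2^H with H the Shannon entropy in bits; zero-frequency terms
    contribute nothing.
    """
    prefs = site.pref_array()
    if metric_kind == "ddg":
        weights = np.power(10.0, -prefs)
    elif metric_kind == "preference":
        if np.any(prefs < 0):
            bad = [a for a in AMINO_ACIDS if site.preferences[a] < 0]
            raise ValueError(f"residue {site.residue_number}: negative "
                             f"preference for {bad} under metric 'preference'")
        weights = prefs
    else:
        raise ValueError(f"unknown metric_kind {metric_kind!r}")
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"residue {site.residue_number}: all preferences zero")
    f = weights / total
    nz = f[f > 0]
    entropy = -float(np.sum(nz * np.log2(nz)))
    return float(2.0 ** entropy)


def fill_kstar(table: PreferenceTable) -> None:
    """Compute k* in place for every site that lacks a user-provided value."""
    for site in table.sites:
        if site.kstar is None:
            site.kstar = compute_kstar(site, table.metric_kind)
            site.kstar_source = "computed"
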