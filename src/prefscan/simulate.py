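"""Synthetic preference tables and alignments with planted structure.

Three site archetypes cover what the screen must distinguish:

* planted — the response is slope * descriptor + Gaussian noise, so one
  catalog scale truly shapes the site;
* null — i.i.d. Gaussian responses with no descriptor dependence (the
  type-I-error control case);
* conserved — a single amino acid tolerated, giving k* near 1 (the
  active-site-like case the tolerance flags must catch).

Alignments are sampled column-wise from explicit amino acid profiles, which
lets the alignment-to-ddG conversion be checked against closed forms.  All
generators take explicit seeds and share no global random state.  The noise
model is Gaussian on the response scale, matching the least-squares
assumptions of the screen so that power and error rates are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .descriptors import AMINO_ACIDS, DescriptorCatalog, load_catalog
from .preference_io import PreferenceTable, SiteRecord


@dataclass
class SiteTruth:
    residue_number: int
    label: str                       # "planted" | "null" | "conserved"
    descriptor_id: str | None = None
    slope: float | None = None
    noise_sd: float | None = None


@dataclass
class SyntheticTruth:
    """Ground truth per synthetic site, for scoring recovery."""

    sites: list[SiteTruth]
    seed: int

    def by_label(self, label: str) -> list[SiteTruth]:
        return [s for s in self.sites if s.label == label]

    def to_tsv(self) -> str:
        lines = ["residue\tlabel\tdescriptor\tslope\tnoise_sd"]
        for s in self.sites:
            lines.append("\t".join([
                str(s.residue_number), s.label,
                s.descriptor_id or "-",
                "" if s.slope is None else repr(s.slope),
                "" if s.noise_sd is None else repr(s.noise_sd),
            ]))
        return "\n".join(lines) + "\n"


def _encode_site(y: np.ndarray, residue_number: int, metric_kind: str,
                 rng: np.random.Generator) -> SiteRecord:
    """Turn a response vector (higher = more favored) into a SiteRecord."""
    if metric_kind == "ddg":
        wt_idx = int(np.argmax(y))
        ddg = -(y - y[wt_idx])          # wt at exactly 0, favored < wt impossible
        prefs = dict(zip(AMINO_ACIDS, ddg.tolist()))
        return SiteRecord(AMINO_ACIDS[wt_idx], residue_number, prefs)
    shifted = y - y.min()               # non-negative preferences
    wt_idx = int(np.argmax(shifted))
    return SiteRecord(AMINO_ACIDS[wt_idx], residue_number,
                      dict(zip(AMINO_ACIDS, shifted.tolist())))


def gen_planted_table(n_sites: int, descriptor_id: str, slope: float,
                      noise_sd: float, seed: int,
                      metric_kind: str = "ddg",
                      catalog: DescriptorCatalog | None = None
                      ) -> tuple[PreferenceTable, SyntheticTruth]:
    """Sites whose response is ``slope * descriptor + N(0, noise_sd)``."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    catalog = catalog or load_catalog()
    d = catalog.get(descriptor_id).as_array()
    rng = np.random.default_rng(seed)
    sites, truths = [], []
    for num in range(1, n_sites + 1):
        y = slope * d + rng.normal(0.0, noise_sd, size=20)
        sites.append(_encode_site(y, num, metric_kind, rng))
        truths.append(SiteTruth(num, "planted", descriptor_id, slope, noise_sd))
    table = PreferenceTable(sites, metric_kind=metric_kind,
                            source=f"synthetic:planted:{descriptor_id}")
    return table, SyntheticTruth(truths, seed)


def gen_null_table(n_sites: int, noise_sd: float = 1.0, seed: int = 0,
                   metric_kind: str = "ddg") -> PreferenceTable:
    """Sites with i.i.d. Gaussian responses — no descriptor dependence."""
    rng = np.random.default_rng(seed)
    sites = [
        _encode_site(rng.normal(0.0, noise_sd, size=20), num, metric_kind, rng)
        for num in range(1, n_sites + 1)
    ]
    return PreferenceTable(sites, metric_kind=metric_kind,
                           source="synthetic:null")


def gen_conserved_table(n_sites: int, seed: int = 0) -> PreferenceTable:
    """One-hot sites: a single tolerated amino acid per site (k* = 1)."""
    rng = np.random.default_rng(seed)
    sites = []
    for num in range(1, n_sites + 1):
        wt = AMINO_ACIDS[rng.integers(20)]
        prefs = {a: (1.0 if a == wt else 0.0) for a in AMINO_ACIDS}
        sites.append(SiteRecord(wt, num, prefs))
    return PreferenceTable(sites, metric_kind="preference",
                           source="synthetic:conserved")


def gen_mixture_table(n_sites: int = 500, seed: int = 0,
                      planted_frac: float = 0.6, null_frac: float = 0.3,
                      noise_rel: float = 0.1, planted_sets: tuple = (1,),
                      catalog: DescriptorCatalog | None = None
                      ) -> tuple[PreferenceTable, SyntheticTruth]:
    """Planted / null / conserved mixture on the ddG scale.

    Planted sites draw a random descriptor from ``planted_sets`` and a
    random trend sign; slope magnitudes are set so the noise-free response
    has unit spread (|slope| = 1 / sd(descriptor)), and the noise sd is
    ``noise_rel * |slope| * sd(descriptor)`` — i.e. noise_rel is the
    noise-to-signal ratio.  Conserved sites are one-hot encoded as ddG
    (wild type 0, every substitution heavily penalised).
    """
    catalog = catalog or load_catalog()
    pool = [t for t in catalog.tables if t.set_id in set(planted_sets)]
    if not pool:
        raise ValueError(f"no descriptors in sets {planted_sets}")
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_frac * n_sites))
    n_null = int(round(null_frac * n_sites))

    sites, truths = [], []
    for num in range(1, n_sites + 1):
        if num <= n_planted:
            desc = pool[rng.integers(len(pool))]
            d = desc.as_array()
            sign = 1.0 if rng.random() < 0.5 else -1.0
            slope = sign / float(np.std(d))
            noise_sd = noise_rel * abs(slope) * float(np.std(d))
            y = slope * d + rng.normal(0.0, noise_sd, size=20)
            sites.append(_encode_site(y, num, "ddg", rng))
            truths.append(SiteTruth(num, "planted", desc.descriptor_id,
                                    slope, noise_sd))
        elif num <= n_planted + n_null:
            y = rng.normal(0.0, 1.0, size=20)
            sites.append(_encode_site(y, num, "ddg", rng))
            truths.append(SiteTruth(num, "null"))
        else:
            wt = AMINO_ACIDS[rng.integers(20)]
            ddg = {a: (0.0 if a == wt else 10.0) for a in AMINO_ACIDS}
            sites.append(SiteRecord(wt, num, ddg))
            truths.append(SiteTruth(num, "conserved"))
    table = PreferenceTable(sites, metric_kind="ddg",
                            source="synthetic:mixture")
    return table, SyntheticTruth(truths, seed)


def gen_alignment(n_sequences: int, column_profiles: list[dict[str, float]],
                  seed: int = 0, gap_fraction: float = 0.0,
                  query: str | None = None) -> list[SeqRecord]:
    """Sample a gapped alignment column-wise from amino acid profiles.

    Each of ``n_sequences`` homolog rows draws its residue at column j
    multinomially from ``column_profiles[j]`` (then becomes a gap with
    probability ``gap_fraction``).  The first returned record, id
    ``"query"``, is the ungapped reference sequence: ``query`` if given,
    else the modal amino acid of each profile.  The query is not one of the
    ``n_sequences`` sampled rows.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_cols = len(column_profiles)
    if query is None:
        query = "".join(max(p, key=p.get) for p in column_profiles)
    if len(query) != n_cols:
        raise ValueError("query length must match number of column profiles")

    columns = []
    for profile in column_profiles:
        aas = list(profile)
        probs = np.array([profile[a] for a in aas], dtype=float)
        probs = probs / probs.sum()
        drawn = rng.choice(len(aas), size=n_sequences, p=probs)
        col = np.array([aas[i] for i in drawn])
        if gap_fraction > 0:
            col[rng.random(n_sequences) < gap_fraction] = "-"
        columns.append(col)
    matrix = np.stack(columns, axis=1)

    records = [SeqRecord(Seq(query), id="query", description="")]
    records += [
        SeqRecord(Seq("".join(matrix[i])), id=f"seq{i + 1}", description="")
        for i in range(n_sequences)
    ]
    return records
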