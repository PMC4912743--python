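"""Site classification, descriptor summaries, sequence and structure maps.

A screened table partitions into four exhaustive, exclusive classes: sites
explained by at least one descriptor, and unexplained sites split by their
tolerance to substitution k* (very low < k_low, very high > k_high, or
intermediate).  Summaries count how often each descriptor was the best fit,
split by trend sign.  Structure outputs are PyMOL / VMD selection strings
and PDB files whose B-factor column carries a per-residue value (k*, an
adjusted p, ...) for coloring in any molecular viewer.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import pandas as pd

from .descriptors import DescriptorCatalog
from .fitting import ScreenConfig, SiteFit
from .preference_io import PreferenceTable


class SiteClass(str, enum.Enum):
    EXPLAINED = "explained"
    UNEXPLAINED_LOW_TOLERANCE = "unexplained_low_tolerance"
    UNEXPLAINED_HIGH_TOLERANCE = "unexplained_high_tolerance"
    UNEXPLAINED_MID = "unexplained_mid"


@dataclass
class AnalysisReport:
    """Everything a screen produced: all fits, best fits, classes, config."""

    table: PreferenceTable
    catalog: DescriptorCatalog
    config: ScreenConfig
    all_fits: list[SiteFit]
    best_fits: dict[int, SiteFit]
    classes: dict[int, SiteClass] = field(default_factory=dict)


def classify_sites(report: AnalysisReport, k_low: float = 4.0,
                   k_high: float = 16.0) -> dict[int, SiteClass]:
    """Partition sites: explained, else by extreme/intermediate tolerance."""
    classes: dict[int, SiteClass] = {}
    for site in report.table.sites:
        num = site.residue_number
        if num in report.best_fits:
            classes[num] = SiteClass.EXPLAINED
        elif site.kstar is not None and site.kstar < k_low:
            classes[num] = SiteClass.UNEXPLAINED_LOW_TOLERANCE
        elif site.kstar is not None and site.kstar > k_high:
            classes[num] = SiteClass.UNEXPLAINED_HIGH_TOLERANCE
        else:
            classes[num] = SiteClass.UNEXPLAINED_MID
    return classes


def summarize_by_descriptor(report: AnalysisReport,
                            grouped: bool = False
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor pick frequencies and the four-class site partition.

    Returns ``(per_descriptor, class_summary)``.  The per-descriptor table
    counts sites whose BEST fit used each descriptor, split by trend sign,
    with percentages over all sites with data and the share of explained
    sites.  With ``grouped=True`` descriptors are pooled by set.  The class
    summary gives the four-way partition as counts and percentages over all
    sites.
    """
    n_sites = len(report.table.sites)
    n_explained = len(report.best_fits)

    rows = []
    universe = [t for t in report.catalog.tables
                if t.set_id in report.config.selected_sets]
    if grouped:
        keys = sorted({t.set_id for t in universe})
        label = {k: f"Set {k}" for k in keys}
        key_of = {t.descriptor_id: t.set_id for t in universe}
    else:
        keys = [t.descriptor_id for t in universe]
        label = {t.descriptor_id: t.display_name for t in universe}
        key_of = {t.descriptor_id: t.descriptor_id for t in universe}
    counts = {k: {"positive": 0, "negative": 0} for k in keys}
    for fit in report.best_fits.values():
        counts[key_of[fit.descriptor_id]][fit.trend] += 1
    for k in keys:
        pos, neg = counts[k]["positive"], counts[k]["negative"]
        total = pos + neg
        rows.append({
            "descriptor": label[k],
            "n_positive": pos,
            "n_negative": neg,
            "n_total": total,
            "pct_of_sites": 100.0 * total / n_sites if n_sites else 0.0,
            "pct_of_explained": (100.0 * total / n_explained
                                 if n_explained else 0.0),
        })
    per_descriptor = pd.DataFrame(rows)

    class_rows = []
    for cls in SiteClass:
        n = sum(1 for c in report.classes.values() if c is cls)
        class_rows.append({
            "class": cls.value,
            "n_sites": n,
            "pct_of_sites": 100.0 * n / n_sites if n_sites else 0.0,
        })
    class_summary = pd.DataFrame(class_rows)
    return per_descriptor, class_summary


def sequence_map(report: AnalysisReport) -> str:
    """Tab-delimited per-residue track, ordered by residue number.

    Columns: residue number, wild-type amino acid, k*, class, best descriptor
    (``-`` when unexplained), trend, adjusted p, slope.
    """
    header = ["residue", "wt", "kstar", "class", "best_descriptor", "trend",
              "p_adj", "slope"]
    lines = ["\t".join(header)]
    for site in sorted(report.table.sites, key=lambda s: s.residue_number):
        num = site.residue_number
        fit = report.best_fits.get(num)
        kstar = "" if site.kstar is None else f"{site.kstar:.4g}"
        cls = report.classes.get(num, SiteClass.UNEXPLAINED_MID).value
        if fit is None:
            row = [str(num), site.wt_aa, kstar, cls, "-", "-", "", ""]
        else:
            row = [str(num), site.wt_aa, kstar, cls, fit.descriptor_id,
                   fit.trend, f"{fit.model.p_adj:.6g}",
                   f"{fit.model.slope:.6g}"]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def structure_selections(report: AnalysisReport, chain: str,
                         dialect: str = "pymol",
                         descriptor_id: str | None = None,
                         trend: str | None = None) -> str:
    """Prebuilt residue selections for PyMOL or VMD.

    Selects the residues whose best fit matches the descriptor/trend filter
    (both optional; omitted parts match everything), sorted ascending.
    """
    if dialect not in ("pymol", "vmd"):
        raise ValueError(f"dialect must be 'pymol' or 'vmd', got {dialect!r}")
    residues = sorted(
        num for num, fit in report.best_fits.items()
        if (descriptor_id is None or fit.descriptor_id == descriptor_id)
        and (trend is None or fit.trend == trend)
    )
    if not residues:
        return "# empty selection\n"
    name_parts = [descriptor_id or "best_fit"]
    if trend:
        name_parts.append("pos" if trend == "positive" else "neg")
    name = "_".join(name_parts)
    if dialect == "pymol":
        resi = "+".join(str(r) for r in residues)
        return f"select {name}, chain {chain} and resi {resi}\n"
    resid = " ".join(str(r) for r in residues)
    return f"chain {chain} and resid {resid}\n"


def bfactor_annotate(coordinates: str, chain: str,
                     values: dict[int, float], default: float = 0.0) -> str:
    """Rewrite the B-factor column of PDB text with per-residue values.

    Atoms of the given chain take ``values[residue_number]`` (``default``
    when the residue is absent from the mapping); every other character of
    every line is preserved byte-for-byte.  Raises if the structure and the
    value mapping share no residue number (a numbering offset is the usual
    culprit).
    """
    lines = coordinates.splitlines(keepends=True)
    if not any(ln.startswith(("ATOM", "HETATM")) for ln in lines):
        raise ValueError("no ATOM/HETATM records: input is not PDB-format text")
    chain_residues: set[int] = set()
    out: list[str] = []
    for ln in lines:
        if ln.startswith(("ATOM", "HETATM")) and len(ln) >= 66:
            ln_chain = ln[21]
            try:
                resnum = int(ln[22:26])
            except ValueError:
                out.append(ln)
                continue
            if ln_chain == chain:
                chain_residues.add(resnum)
                b = values.get(resnum, default)
                ln = ln[:60] + f"{b:6.2f}" + ln[66:]
        out.append(ln)
    if values and not (chain_residues & set(values)):
        raise ValueError(
            f"no residue number of chain {chain!r} matches the value mapping; "
            "check for a numbering offset between table and structure"
        )
    return "".join(out)


def _fits_frame(fits: list[SiteFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "residue": f.residue_number,
            "descriptor": f.descriptor_id,
            "order": f.model.order,
            "intercept": f.model.coefficients[0],
            "slope": f.model.coefficients[1],
            "quadratic": (f.model.coefficients[2]
                          if f.model.order == 2 else None),
            "r": f.model.r,
            "rmse": f.model.rmse,
            "p_raw": f.model.p_raw,
            "p_adj": f.model.p_adj,
            "trend": f.trend,
        }
        for f in fits
    ], columns=["residue", "descriptor", "order", "intercept", "slope",
                "quadratic", "r", "rmse", "p_raw", "p_adj", "trend"])


def export_report(report: AnalysisReport, out_dir, fmt: str = "tsv") -> list:
    """Write all-fits, best-fits, summary and sequence-map files.

    ``fmt`` is ``"tsv"`` or ``"json"``; JSON mirrors the TSV content.
    Returns the written paths.
    """
    from pathlib import Path

    if fmt not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_df = _fits_frame(report.all_fits)
    best_df = _fits_frame(sorted(report.best_fits.values(),
                                 key=lambda f: f.residue_number))
    per_desc, class_summary = summarize_by_descriptor(report)
    seq_map = sequence_map(report)

    written = []
    if fmt == "tsv":
        for name, df in [("all_fits", all_df), ("best_fits", best_df),
                         ("summary_by_descriptor", per_desc),
                         ("summary_by_class", class_summary)]:
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
        path = out_dir / "sequence_map.tsv"
        path.write_text(seq_map)
        written.append(path)
    else:
        payload = {
            "all_fits": all_df.to_dict(orient="records"),
            "best_fits": best_df.to_dict(orient="records"),
            "summary_by_descriptor": per_desc.to_dict(orient="records"),
            "summary_by_class": class_summary.to_dict(orient="records"),
            "sequence_map": seq_map,
            "config": {
                "alpha": report.config.alpha,
                "selected_sets": sorted(report.config.selected_sets),
                "quadratic": report.config.quadratic,
                "f_alpha": report.config.f_alpha,
                "r_min": report.config.r_min,
                "rmse_max": report.config.rmse_max,
                "k_low": report.config.k_low,
                "k_high": report.config.k_high,
                "metric_kind": report.table.metric_kind,
            },
        }
        path = out_dir / "report.json"
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)
    return written
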