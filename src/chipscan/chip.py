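"""CHIP annotation: somatic calls -> per-sample CHIP variables.

A sample is a CHIP carrier when it holds at least one somatic variant in a
whitelisted driver gene at a variant allele fraction (VAF) strictly greater
than 2%; a clone is "large" at VAF strictly greater than 10%.  The derived
per-sample variables are the composite indicator, per-driver-gene
indicators, the large-clone indicator, and the driver count.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

VAF_MIN = 0.02          # carrier threshold, strict ">"
LARGE_CLONE_VAF = 0.10  # large-clone threshold, strict ">"


@dataclass
class Whitelist:
    """Driver genes and qualifying variant classes."""

    genes: dict[str, set[str] | None]  # gene -> allowed classes, None = any
    vaf_min: float = VAF_MIN
    large_clone_vaf: float = LARGE_CLONE_VAF
    version: int | str = 0

    def allows(self, gene: str, variant_class: str | None) -> bool:
        if gene not in self.genes:
            return False
        classes = self.genes[gene]
        return classes is None or variant_class in classes


def load_whitelist(path: str | None = None) -> Whitelist:
    """Load a whitelist YAML; default is the packaged common-driver list."""
    if path is None:
        src = importlib.resources.files("chipscan").joinpath("data/chip_whitelist.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    genes = {}
    for g, cfg in raw["genes"].items():
        classes = (cfg or {}).get("classes", "any")
        genes[g] = None if classes == "any" else set(classes)
    return Whitelist(genes=genes,
                     vaf_min=float(raw.get("vaf_min", VAF_MIN)),
                     large_clone_vaf=float(raw.get("large_clone_vaf", LARGE_CLONE_VAF)),
                     version=raw.get("version", 0))


@dataclass
class AnnotationReport:
    """Exclusion accounting: retained + sum(excluded by reason) = input rows."""

    n_input: int = 0
    n_retained: int = 0
    excluded: dict[str, int] = field(default_factory=dict)


def annotate_chip_variants(calls: pd.DataFrame,
                           whitelist: Whitelist | None = None,
                           vaf_min: float | None = None,
                           ) -> tuple[pd.DataFrame, AnnotationReport]:
    """Filter raw somatic calls to annotated CHIP calls.

    Keeps rows whose gene (and variant class, if restricted) is whitelisted
    and whose VAF is strictly greater than ``vaf_min``.  Every exclusion is
    counted by reason.  Idempotent: re-annotating the output changes nothing.
    """
    whitelist = whitelist or load_whitelist()
    vaf_min = whitelist.vaf_min if vaf_min is None else vaf_min
    report = AnnotationReport(n_input=len(calls))
    if len(calls) == 0:
        return calls.copy(), report
    vaf = pd.to_numeric(calls["vaf"], errors="coerce")
    if vaf.isna().any() or (vaf <= 0).any() or (vaf > 1).any():
        raise ValueError("vaf column must be numeric in (0, 1]")
    keep = np.ones(len(calls), dtype=bool)
    in_list = calls["gene"].map(lambda g: g in whitelist.genes).to_numpy()
    classes_ok = np.array([
        whitelist.allows(g, c) for g, c in
        zip(calls["gene"], calls.get("variant_class", pd.Series([None] * len(calls))))
    ])
    low_vaf = (vaf <= vaf_min).to_numpy()

    reasons = {
        "gene_not_whitelisted": ~in_list,
        "variant_class_excluded": in_list & ~classes_ok,
        "vaf_at_or_below_threshold": in_list & classes_ok & low_vaf,
    }
    for reason, mask in reasons.items():
        n = int(mask.sum())
        if n:
            report.excluded[reason] = n
        keep &= ~mask
    out = calls.loc[keep].reset_index(drop=True)
    report.n_retained = len(out)
    return out, report


def derive_chip_variables(calls: pd.DataFrame, sample_ids: list[str],
                          gene_columns: list[str] | None = None,
                          large_vaf: float = LARGE_CLONE_VAF) -> pd.DataFrame:
    """Per-sample CHIP variables from annotated calls.

    Returns one row per sample in ``sample_ids`` with ``has_chip``,
    one 0/1 column per driver gene, ``has_large_chip`` (any call with
    VAF strictly above ``large_vaf``), and ``n_drivers`` (distinct driver
    genes).  Non-carriers get all-zero indicators.
    """
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample ids must be unique")
    known = set(sample_ids)
    if len(calls):
        unknown = set(calls["sample_id"]) - known
        if unknown:
            raise ValueError(f"calls reference unknown samples: "
                             f"{sorted(unknown)[:5]}")
    genes = gene_columns or sorted(set(calls["gene"])) if len(calls) else \
        (gene_columns or [])
    out = pd.DataFrame({"sample_id": sample_ids})
    out["has_chip"] = 0
    for g in genes:
        out[g] = 0
    out["has_large_chip"] = 0
    out["n_drivers"] = 0
    if len(calls) == 0:
        return out
    out = out.set_index("sample_id")
    per_gene = calls.groupby("sample_id")["gene"].agg(set)
    out.loc[per_gene.index, "has_chip"] = 1
    out.loc[per_gene.index, "n_drivers"] = per_gene.map(len).astype(int)
    for g in genes:
        hit = per_gene.index[per_gene.map(lambda s: g in s)]
        out.loc[hit, g] = 1
    large = calls.loc[calls["vaf"] > large_vaf, "sample_id"].unique()
    out.loc[large, "has_large_chip"] = 1
    return out.reset_index()
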