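"""Bundled fixtures transcribed from the printed validation tables, and the
significance report over them."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from helix_ieg.probe_validation import bonferroni, mann_whitney_exact


def _data_path(name: str):
    return resources.files("helix_ieg.data") / name


def load_probe_table() -> pd.DataFrame:
    """The published junction-spanning ISH probe (contig id, sequence, length, GC)."""
    return pd.read_csv(_data_path("table4_probe.tsv"), sep="\t",
                       dtype={"contig_id": str})


def load_primer_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("table5_primers.tsv"), sep="\t")


def load_validation_values() -> pd.DataFrame:
    """qPCR relative expression, behavioral latencies and IHC fluorescence
    intensities (tidy: assay, group, value; missing values are NA)."""
    return pd.read_csv(_data_path("table7_values.tsv"), sep="\t",
                       na_values=["NA"])


def fig4_report(values: pd.DataFrame | None = None) -> dict:
    """All validation significance calls from the printed measurement values.

    One-sided exact Mann-Whitney tests for: qPCR stimulated > control; Pa2
    trained > control; stimulated LPa3 > non-stimulated RPa3; serotonergic
    paired > unpaired; Pa2 paired vs unpaired (reported non-significant); and
    Bonferroni-corrected (m = 2 comparisons) paired-CS approach latency vs
    control-CS and unpaired-CS.
    """
    if values is None:
        values = load_validation_values()

    def grp(assay: str, group: str):
        v = values.query("assay == @assay and group == @group")["value"]
        return v.dropna().to_numpy()

    def one_sided(assay: str, hi: str, lo: str, alpha: float) -> dict:
        r = mann_whitney_exact(grp(assay, hi), grp(assay, lo), "greater")
        return {"u": r.u, "n1": r.n1, "n2": r.n2, "p": r.p_value,
                "alpha": alpha, "significant": r.p_value < alpha}

    report = {
        "qpcr_stimulated_gt_control": one_sided("qpcr", "stimulated", "control", 0.05),
        "pa2_trained_gt_control": one_sided("pa2_training", "trained", "control", 0.005),
        "lpa3_gt_rpa3": one_sided("pa3_unilateral", "stimulated", "control", 0.005),
        "serotonergic_paired_gt_unpaired": one_sided("serotonergic", "paired",
                                                     "unpaired", 0.005),
        "pa2_paired_vs_unpaired": one_sided("pa2_pairing", "paired", "unpaired", 0.005),
    }
    # behavior: paired-CS latency against the two comparison groups, Bonferroni
    raw = [mann_whitney_exact(grp("behavior_cs", "paired"),
                              grp("behavior_cs", other), "greater").p_value
           for other in ("control", "unpaired")]
    adj = bonferroni(raw, m=len(raw))
    for name, p_raw, p_adj in zip(("behavior_paired_cs_gt_control_cs",
                                   "behavior_paired_cs_gt_unpaired_cs"), raw, adj):
        report[name] = {"p": float(p_raw), "p_bonferroni": float(p_adj),
                        "alpha": 0.05, "significant": bool(p_adj < 0.05)}
    return report
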