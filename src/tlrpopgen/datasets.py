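"""Published per-gene tables of the newt TLR study, shipped as inputs.

The study's per-gene sequence data are not deposited, but its per-gene
statistics tables are printed in full: long-term divergence (dN/dS against
*Notophthalmus*), species-wide polymorphism (including the SNiPRE constraint
estimate *f*, consumed here as an input), per-lineage polymorphism and the
neutrality-test values for *L. montandoni* (Lm) and *L. vulgaris graecus*
(Lvg).  :func:`comparative_statistics` recomputes the study's cross-gene
comparisons from those columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .comparisons import (
    pearson_correlation_test,
    split_by_class,
    welch_t_test,
)


def _load(name):
    with resources.files("tlrpopgen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_divergence_table() -> pd.DataFrame:
    """Long-term dN/dS per gene (16 genes; TLR12 has no alignment)."""
    return _load("divergence_dnds.tsv")


def load_specieswide_table() -> pd.DataFrame:
    """Species-wide polymorphism, MK/NI and constraint f (11 genes)."""
    return _load("specieswide_polymorphism.tsv")


def load_lineage_table() -> pd.DataFrame:
    """Per-lineage polymorphism (Lm and Lvg columns, 11 genes)."""
    return _load("lineage_polymorphism.tsv")


def load_tests_table() -> pd.DataFrame:
    """Per-lineage MK, HKA, Tajima's D and Fay & Wu's H values (11 genes)."""
    return _load("neutrality_tests.tsv")


def comparative_statistics() -> dict:
    """Recompute the study's cross-gene comparative statistics.

    Returns a dict of :class:`~tlrpopgen.comparisons.ComparisonResult` plus
    the two column means, keyed by short descriptive names:

    * ``dnds_na_vs_nonna`` — Welch t, long-term dN/dS between sensing
      classes, TLR13 excluded as the partial-sequence outlier (TLR12 has no
      estimate, TLR19 is unassigned);
    * ``f_na_vs_nonna`` — Welch t, SNiPRE constraint f between classes;
    * ``dnds_f_correlation`` — Pearson r between dN/dS and f over the 10
      genes with both values (TLR13 excluded);
    * ``pi_na_vs_nonna`` — Welch t, species-wide pi between classes;
    * ``pi_lm_vs_lvg`` — Welch t, per-lineage pi (Lm - Lvg);
    * ``tajima_d_lvg_vs_lm`` — Welch t, per-lineage Tajima's D in the
      (Lvg - Lm) group order;
    * ``mean_pi_specieswide`` — mean species-wide pi across the 11 genes;
    * ``mean_tajima_d_lm`` — mean Tajima's D across the 11 genes in Lm.
    """
    t1 = load_divergence_table()
    t2 = load_specieswide_table()
    t3 = load_lineage_table()
    t4 = load_tests_table()

    dnds = dict(zip(t1["gene"], t1["dnds"]))
    na, nonna = split_by_class(dnds, exclude=("TLR13",))
    res = {"dnds_na_vs_nonna": welch_t_test(na, nonna, "dnds_na_vs_nonna")}

    f = dict(zip(t2["gene"], t2["f"]))
    na, nonna = split_by_class(f)
    res["f_na_vs_nonna"] = welch_t_test(na, nonna, "f_na_vs_nonna")

    genes10 = [g for g in t2["gene"] if g != "TLR13"]
    res["dnds_f_correlation"] = pearson_correlation_test(
        [dnds[g] for g in genes10], [f[g] for g in genes10], "dnds_f_correlation"
    )

    pi = dict(zip(t2["gene"], t2["pi"]))
    na, nonna = split_by_class(pi)
    res["pi_na_vs_nonna"] = welch_t_test(na, nonna, "pi_na_vs_nonna")

    res["pi_lm_vs_lvg"] = welch_t_test(t3["pi_lm"], t3["pi_lvg"], "pi_lm_vs_lvg")
    res["tajima_d_lvg_vs_lm"] = welch_t_test(
        t4["D_lvg"], t4["D_lm"], "tajima_d_lvg_vs_lm"
    )
    res["mean_pi_specieswide"] = float(t2["pi"].mean())
    res["mean_tajima_d_lm"] = float(t4["D_lm"].mean())
    return res
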