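"""Shared fixtures: a seeded default synthetic cohort and the full
differential-expression chain run once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncrecur import recurrence as R
from lncrecur.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic matched cohort at a fixed seed."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def de_chain(cohort):
    """Per-patient calls, recurrence, cohort-level tests and the final
    intersected recurrent sets for both contrasts, computed once."""
    b = cohort
    uni = b.truth.lnc_universe
    lib = b.counts.sum(axis=0)
    out = {"universe": uni}
    for contrast, r_min, sub_seed in (("tumour_vs_normal", 8, 7),
                                      ("pvtt_vs_tumour", 4, 8)):
        calls = R.per_patient_calls(b.counts.loc[uni], b.design, contrast,
                                    seed=sub_seed, lib_sizes=lib)
        rec = R.recurrence_counts(calls, uni)
        out[contrast] = {"calls": calls, "recurrence": rec, "r_min": r_min}
    wil = R.wilcoxon_de(b.fpkm.loc[uni], b.design, "tumour_vs_normal")
    nbw = R.nb_wald_de(b.counts.loc[uni], b.design, "tumour_vs_normal")
    out["wilcoxon"] = wil
    out["nb_wald"] = nbw
    rec_t = out["tumour_vs_normal"]["recurrence"]
    gf_sets = (set(rec_t.index[rec_t["n_up"] >= 8]),
               set(rec_t.index[rec_t["n_down"] >= 8]))
    w_sets = (set(wil.index[wil["direction"] == "up"]),
              set(wil.index[wil["direction"] == "down"]))
    n_sets = (set(nbw.index[nbw["direction"] == "up"]),
              set(nbw.index[nbw["direction"] == "down"]))
    out["final_tumour"] = R.intersect_methods(gf_sets, n_sets, w_sets,
                                              "tumour_vs_normal")
    rec_p = out["pvtt_vs_tumour"]["recurrence"]
    out["final_pvtt"] = (set(rec_p.index[rec_p["n_up"] >= 4]),
                         set(rec_p.index[rec_p["n_down"] >= 4]))
    return out


@pytest.fixture(scope="session")
def null_cohorts():
    """Twenty small cohorts with zero planted effects, for calibration."""
    cfg = SyntheticConfig(
        n_coding=60, n_ref_lncrna=40, n_lncrna=120, n_decoys=0,
        n_tumour_up=0, n_tumour_down=0, n_pvtt_up=0, n_pvtt_down=0,
        n_cnv_features=0, n_meth_features=0, n_modules=0)
    return [generate_cohort(cfg, seed=100 + i) for i in range(20)]
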