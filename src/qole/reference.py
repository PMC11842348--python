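"""Published triangulation inputs for the QOL-E pooled four-trial cohort.

These are the printed inputs of the published MWPC triangulation for the
QOL-E (anchor-group sample sizes and mean/median change scores for the
>=1-level improvement and worsening groups on the two retained anchors,
SEM, half the baseline SD, and each domain's minimum possible change), on
the 0-100 score scale.  They let the triangulation rule be exercised on
the real analysis inputs without access to the sponsor-held patient-level
data.  Sexual well-being is absent: its responsiveness was inadequate and
no threshold was triangulated for it.

The eCDF separation outcomes are recorded as published: the improvement
side did not separate from no change for the functional and social/family
well-being domains, so their improvement-side anchor estimates contribute
nothing to the triangulation.
"""

from __future__ import annotations

from .mwpc import TriangulationInputs


def _inputs(score, sem, half_sd, mpc, item1, item29, imp_sep=True, wors_sep=True):
    anchors = {}
    for name, est in (("item1", item1), ("qlq_item29", item29)):
        anchors[name] = {
            "improvement": dict(zip(("n", "mean", "median"), est[0])),
            "worsening": dict(zip(("n", "mean", "median"), est[1])),
        }
    return TriangulationInputs(
        score=score, sem=sem, half_sd=half_sd, mpc=mpc,
        anchor_estimates=anchors,
        ecdf_separated={"improvement": imp_sep, "worsening": wors_sep},
    )


#: score -> TriangulationInputs, published pooled-cohort values
REFERENCE_TRIANGULATION_INPUTS: dict[str, TriangulationInputs] = {
    "FIS": _inputs("FIS", sem=12.6, half_sd=10.7, mpc=12.5,
                   item1=((50, 14.8, 12.5), (57, -11.4, -12.5)),
                   item29=((29, 15.1, 12.5), (28, -18.8, -25.0))),
    "FUN": _inputs("FUN", sem=21.1, half_sd=16.2, mpc=11.1,
                   item1=((49, 16.3, 0.0), (56, -21.6, -22.2)),
                   item29=((28, 13.1, 0.0), (28, -24.6, -16.7)),
                   imp_sep=False),
    "SOC": _inputs("SOC", sem=18.1, half_sd=18.8, mpc=25.0,
                   item1=((39, 13.5, 0.0), (46, -20.1, -12.5)),
                   item29=((23, 8.7, 0.0), (19, -22.4, 0.0)),
                   imp_sep=False),
    "FAT": _inputs("FAT", sem=7.5, half_sd=7.0, mpc=4.8,
                   item1=((50, 9.2, 7.1), (57, -8.7, -4.8)),
                   item29=((30, 7.6, 7.1), (28, -18.5, -19.1))),
    "MDSS": _inputs("MDSS", sem=12.9, half_sd=11.9, mpc=2.4,
                    item1=((49, 15.0, 11.9), (56, -9.7, -7.1)),
                    item29=((30, 11.6, 11.9), (26, -13.6, -15.5))),
    "GEN": _inputs("GEN", sem=8.5, half_sd=10.5, mpc=None,
                   item1=((37, 13.8, 8.5), (46, -12.2, -11.3)),
                   item29=((22, 11.6, 7.1), (19, -18.5, -15.0))),
    "ALL": _inputs("ALL", sem=8.9, half_sd=10.6, mpc=None,
                   item1=((36, 14.8, 10.0), (46, -11.3, -8.4)),
                   item29=((22, 11.2, 8.9), (19, -15.6, -15.1))),
    "TOI": _inputs("TOI", sem=10.0, half_sd=10.3, mpc=None,
                   item1=((46, 15.1, 9.5), (55, -14.8, -13.0)),
                   item29=((28, 13.2, 7.1), (26, -19.5, -18.7))),
}
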