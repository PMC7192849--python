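"""Tabulate Convergent Functional Evidence scores and rank biomarkers.

Each biomarker accumulates points across the pipeline: discovery (max
6), literature prioritization (max 12), validation (max 6), three
predictive-testing outcomes (max 8 each), other-disorder evidence (3)
and opposite-direction drug evidence (3) — 54 in total, 36 from the
pipeline's own data and 18 from the literature.
"""

from stressmark import CfeComponents, cfe_total, rank_by_cfe


def components(disc, ext, val, state, first, future, other, drug):
    return CfeComponents(
        discovery_points=disc, cfg_external_points=ext,
        validation_points=val,
        testing_points={"state_high_stress": state,
                        "hosp_first_year": first,
                        "hosp_all_future": future},
        other_disorder_points=other, drug_points=drug,
    )


rows = {
    # a marker surviving every step with strong but not maximal evidence
    "marker_a": components(4, 12, 4, 6, 4, 4, 3, 3),
    # a literature-heavy marker that failed stepwise validation
    "marker_b": components(4, 9, 0, 0, 8, 8, 3, 3),
    # a reference marker with no discovery/validation data at all
    "reference": components(0, 7, 0, 4, 8, 0, 3, 3),
    # the theoretical maximum
    "maximum": components(6, 12, 6, 8, 8, 8, 3, 3),
}

scores = [cfe_total(c, probeset_id=name) for name, c in rows.items()]
print(f"{'marker':<12}{'own data':>10}{'literature':>12}{'total':>8}")
for s in rank_by_cfe(scores):
    print(f"{s.probeset_id:<12}{s.own_data_subtotal:>10g}"
          f"{s.literature_subtotal:>12g}{s.total:>8g}")
print("\nown data (max 36) = discovery + validation + testing;")
print("literature (max 18) = external CFG + other disorders + drugs.")
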