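"""Regenerate the frozen synthetic two-country fixture used by the fitter
oracle tests.  Run from the repository root:

    python scripts/dev/make_fixture.py
    Rscript scripts/dev/lme4_reference.R
"""

from pathlib import Path

from gfrtraj import (
    CountrySpec,
    apply_inclusion_filters,
    generate_cohort,
    well_specified_config,
)

OUT = Path(__file__).resolve().parents[2] / "tests" / "data"


def main() -> None:
    cfg = well_specified_config(
        n_per_country=50,
        seed=20240101,
        tau2=225.0,
        countries=(
            CountrySpec("north", 0.0, (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)),
            CountrySpec("south", 0.0, (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)),
        ),
    )
    baselines, visits, _ = generate_cohort(cfg)
    baselines, visits, counts = apply_inclusion_filters(baselines, visits)
    OUT.mkdir(parents=True, exist_ok=True)
    baselines.to_csv(OUT / "synthetic_two_country_baseline.csv", index=False)
    visits.to_csv(OUT / "synthetic_two_country_visits.csv", index=False)
    print(f"wrote fixture: {len(baselines)} subjects, {len(visits)} visits, {counts}")


if __name__ == "__main__":
    main()
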