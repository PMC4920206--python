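"""Scan both variants across the metabolite panel in each cohort.

Fits, per metabolite, OLS of ln(metabolite + 1) on allele dosage adjusted
for age, sex and measurement phase.  Writes one association panel TSV per
variant per study and prints how many measures reach nominal significance
(p <= 0.05) — the discovery filter applied in the next stage.
"""

from proxymed.assoc import run_scan
from proxymed.synthcohort import CohortTable

from common import DATA_DIR, RESULTS


def main() -> None:
    for study in ("young", "mothers", "women"):
        cohort = CohortTable.from_tsv(DATA_DIR / f"cohort_{study}.tsv")
        for variant in ("rare", "proxy"):
            panel = run_scan(cohort, variant, transform="always")
            out = RESULTS / f"panel_{variant}_{study}.tsv"
            panel.to_tsv(out)
            ok = panel.ok()
            n_nominal = int((ok["p"] <= 0.05).sum())
            print(
                f"{study:8s} {variant:5s}: {len(ok)} measures fit "
                f"({panel.n_skipped} skipped), {n_nominal} nominal at p<=0.05"
            )


if __name__ == "__main__":
    main()
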