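"""Clean prescriptions, build the incident-user cohort and phenotype L-TOT.

Reads the simulated tables from results/simulated/ (run 01_simulate.py
first), runs cleaning -> washout cohort -> L-TOT/discontinuation
classification, writes the per-event phenotypes and the annual series, and
cross-checks the phenotype labels against the generator's planted truth.
"""

from pathlib import Path

from opioid_trends import SimulationConfig, run_phenotype_pipeline
from opioid_trends.synthetic import SyntheticDataset

IN = Path("results/simulated")
OUT = Path("results/phenotype")


def main() -> None:
    cfg = SimulationConfig.from_yaml(IN / "config.yaml")
    ds = SyntheticDataset.read_csv(IN)
    res = run_phenotype_pipeline(ds, cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    res.classified.to_csv(OUT / "phenotypes.csv", index=False)
    res.annual.to_csv(OUT / "annual_series.csv", index=False)
    print(res.annual.round(2).to_string(index=False))
    print(f"cleaning log: {res.log}")

    truth = ds.episodes
    merged = truth.loc[truth.in_cohort].merge(
        res.classified, on=["patient_id", "index_date"], how="outer",
        suffixes=("_truth", ""), indicator=True)
    n_unmatched = int((merged["_merge"] != "both").sum())
    both = merged.loc[merged["_merge"] == "both"]
    n_ltot_mism = int((both["is_ltot_truth"] != both["is_ltot"]).sum())
    n_disc_mism = int(
        (both["is_discontinuer_truth"] != both["is_discontinuer"]).sum())
    print(f"planted-truth check: {n_unmatched} unmatched index events, "
          f"{n_ltot_mism} L-TOT label mismatches, "
          f"{n_disc_mism} discontinuation mismatches")


if __name__ == "__main__":
    main()
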