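"""Generate the synthetic primary-care dataset used by the downstream steps.

Writes patients / prescriptions / events / episodes CSVs (the last is the
planted ground truth) under results/simulated/ at the default study
conditions: ~13k registered patients per year, 2009-2019 study window,
planted L-TOT probability 11.4% and discontinuation probability 4.8%.
"""

from pathlib import Path

from opioid_trends import SimulationConfig, generate_dataset

OUT = Path("results/simulated")


def main() -> None:
    cfg = SimulationConfig()
    ds = generate_dataset(cfg)
    paths = ds.write_csv(OUT)
    cfg.to_yaml(OUT / "config.yaml")
    print(f"seed={cfg.seed}  n_patients={cfg.n_patients}")
    for name, p in paths.items():
        print(f"wrote {p}  ({len(getattr(ds, name))} rows)")
    planted = ds.episodes
    print(f"planted episodes: {len(planted)} "
          f"({int(planted.in_cohort.sum())} cohort-eligible, "
          f"{int(planted.is_ltot.sum())} L-TOT, "
          f"{int(planted.is_discontinuer.sum())} discontinuers)")


if __name__ == "__main__":
    main()
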