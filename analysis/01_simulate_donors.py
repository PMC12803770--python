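#!/usr/bin/env python
"""Generate the synthetic donor registry used by the downstream analyses.

Emulates a Netherlands-like extract: 10,000 donors (half female), 10 visits
each, stable per-donor setpoints (between-donor SD 1.0 g/dL) with capillary
measurement noise (SD 0.70/0.67 g/dL male/female), minimum donation intervals
56/122 days. One percent of donors then have their setpoint moved to
0.5 g/dL below their deferral threshold — the consistently-low subpopulation
the historical-mean algorithm is meant to catch.

Writes scratch/synthetic_visits.csv (regenerable; not a tracked artifact) and
the ground-truth low-donor IDs to scratch/low_mean_donor_ids.txt.
"""

from pathlib import Path

from hbdefer import PolicyConfig, SimConfig, inject_low_mean_donors, simulate_population, write_visits

SEED = 20250923
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)

    cfg = SimConfig(n_donors=10_000, prop_female=0.5, visits_per_donor=10, seed=SEED)
    pop = simulate_population(cfg)
    pop, low_ids = inject_low_mean_donors(pop, 0.01, 0.5, PolicyConfig(), seed=SEED)

    visits_path = scratch / "synthetic_visits.csv"
    write_visits(pop.histories, visits_path)
    (scratch / "low_mean_donor_ids.txt").write_text("\n".join(low_ids) + "\n")

    n_visits = sum(h.n_visits for h in pop.histories)
    print(f"simulated {pop.n_donors} donors, {n_visits} visits -> {visits_path}")
    print(
        f"injected {len(low_ids)} consistently-low donors "
        "(setpoint 0.5 g/dL below threshold)"
    )


if __name__ == "__main__":
    main()
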