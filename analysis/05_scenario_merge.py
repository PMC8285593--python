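"""Retrospective-merge scenario: integrating a third, differently-equipped
site.

Runs the two merge options (site-specific vs mixed training, both
bias-corrected, FLAIR+T1 only) over the three-site cohort, including the
non-imaging unit harmonisation between the heterogeneous covariate tables,
and writes the report under results/merge/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from wmhh import experiments as ex

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "merge"


def main():
    report = ex.run_scenario(ex.default_merge_config(SEED))
    ex.save_report(report, OUT)
    for oid, o in report["options"].items():
        strat = o["config"]["training_strategy"]
        print(f"option {oid} ({strat}): site variance fraction "
              f"{o['elastic_net']['site_fraction']:.4f}, "
              f"JN intersection {o['johnson_neyman']['intersection']}")
    print("\nMixed training should attribute less WMH-volume variance to the")
    print("scanner than site-specific training, and widen the age region in")
    print("which the sites are statistically indistinguishable.")
    print(f"report written to {OUT}")


if __name__ == "__main__":
    main()
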