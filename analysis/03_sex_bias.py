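#!/usr/bin/env python
"""Compare autosomal and X-chromosomal wild ancestry in the admixed target.

Male-biased wild introgression leaves less wild ancestry on the X than on
the autosomes (males transmit no X to sons); the fixture simulates
alpha_auto = 0.25 vs alpha_X = 0.15 and the Z test should pick up the
deficit's sign.
"""

import json
import os

from bovid_admix.fstats import BlockPartition, PopulationSpec, f4_ratio
from bovid_admix.genotypes import read_eigenstrat
from bovid_admix.sexing import sex_bias_test

HERE = os.path.dirname(__file__)
FIXTURES = os.path.join(HERE, "..", "results", "fixtures")


def ratio(prefix, target="admixed"):
    matrix = read_eigenstrat(prefix)
    blocks = BlockPartition.from_panel(matrix.panel)

    def pop(g):
        return PopulationSpec(g, matrix.members_of(g))

    return f4_ratio(pop(target), pop("european_aurochs"),
                    pop("anatolian_domestic"), pop("caucasus_aurochs"),
                    pop("yak"), matrix, blocks)


def main():
    truth = json.load(open(os.path.join(FIXTURES, "sex_biased_truth.json")))
    auto = ratio(os.path.join(FIXTURES, "sex_biased"))
    x = ratio(os.path.join(FIXTURES, "sex_biased_X"))
    res = sex_bias_test(auto, x)
    t = truth["targets"]["admixed"]
    print(f"simulated: alpha_auto = {t['alpha']}, alpha_X = {t['alpha_x']}")
    print(f"estimated: alpha_auto = {auto.estimate:.3f} "
          f"[{auto.ci[0]:.3f}, {auto.ci[1]:.3f}] ({auto.n_sites} sites)")
    print(f"           alpha_X    = {x.estimate:.3f} "
          f"[{x.ci[0]:.3f}, {x.ci[1]:.3f}] ({x.n_sites} sites)")
    print(f"sex-bias Z = {res.z:.2f} (two-sided p = {res.p_value:.3g}); "
          "positive Z = X deficit of wild ancestry, i.e. male-biased "
          "wild gene flow")


if __name__ == "__main__":
    main()
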