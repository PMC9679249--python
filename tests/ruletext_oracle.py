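"""Brute-force oracle: a direct, independent transcription of the
screening and classification rules, written sentence by sentence with no
helpers shared with the package. Used only to cross-check
``orthoexpand.core`` — deliberately plain and un-refactored.
"""

import math


def oracle_label(focal, sisters, outgroups,
                 screen_fold=2.5, category_fold=3.0, min_represented=8):
    """Label one count vector: focal count, two sister counts, outgroups."""
    # --- screen: fold change vs the mean for all other species, > 2.5 ---
    others = list(sisters) + list(outgroups)
    mean_others = sum(others) / len(others)
    if mean_others == 0:
        fc = math.inf if focal > 0 else 0.0
    else:
        fc = focal / mean_others
    if not (fc > screen_fold):
        return "screened_out"

    # --- representation: < min_represented species removed, unless both
    #     sister species are present ---
    n_present = 0
    for count in [focal] + list(sisters) + list(outgroups):
        if count >= 1:
            n_present = n_present + 1
    both_sisters_present = sisters[0] >= 1 and sisters[1] >= 1
    if n_present < min_represented and not both_sisters_present:
        return "screened_out"

    # --- category predicates, straight from the rule text ---
    mean_sisters = (sisters[0] + sisters[1]) / 2
    mean_outgroups = sum(outgroups) / len(outgroups)

    lacking_outgroup_genes = all(o == 0 for o in outgroups)
    absent_in_both_sisters = sisters[0] == 0 and sisters[1] == 0

    # further >3-fold expansion of the focal species over the sister mean
    if mean_sisters == 0:
        further = focal > 0
    else:
        further = focal / mean_sisters > category_fold

    # >3-fold expansion in *all three* family members vs the outgroups
    ancestral = (
        focal > category_fold * mean_outgroups
        and sisters[0] > category_fold * mean_outgroups
        and sisters[1] > category_fold * mean_outgroups
    )

    # >3-fold expansion of the focal species vs the outgroups alone
    if mean_outgroups == 0:
        focal_over_outgroups = focal > 0
    else:
        focal_over_outgroups = focal / mean_outgroups > category_fold

    # (iv)/(v): family-specific — no genes in any outgroup species
    if lacking_outgroup_genes and not absent_in_both_sisters:
        if further:
            return "iv"
        if both_sisters_present:
            return "v"
        return "none"
    # (vi): absent in both sister species, expanded vs the outgroups
    if absent_in_both_sisters and not lacking_outgroup_genes:
        if focal_over_outgroups:
            return "vi"
    # (i): ancestral family-wide expansion plus further focal expansion
    if ancestral and further:
        return "i"
    # (ii): ancestral family-wide expansion only
    if ancestral and not further:
        return "ii"
    # (iii): focal expansion with no evidence of ancestral expansion
    if focal_over_outgroups and not ancestral:
        return "iii"
    return "none"
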