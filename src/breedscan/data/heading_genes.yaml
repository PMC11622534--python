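# Default heading-date gene definitions for the panel.
#
# Each gene lists ordered haplotype rules: "requires" maps "chrom:pos" to the
# alt-allele dosage (0 = reference, 1 = alternative) a line must carry at that
# defining polymorphism; the first fully matching rule wins.  "activity" maps
# haplotype labels to the 0/1 activity code (0 = lower activity, 1 = higher
# activity) and "effect_sign" is the expected sign of the correlation between
# the activity code and days-to-heading ("+" = active haplotype delays
# heading, "-" = active haplotype promotes early heading).
#
# Hd1 has four haplotypes: B (ancestral, functional), A (36-bp deletion,
# functional), C and D (2-bp and 43-bp deletions, null).  The three deletions
# are represented as biallelic tag SNPs at the listed positions; a line with
# none of the tags is Hap A.
genes:
- name: Hd1
  chromosome: 6
  effect_sign: "+"
  haplotypes:
  - label: B
    requires: {"6:9336861": 1}
  - label: C
    requires: {"6:9337236": 1}
  - label: D
    requires: {"6:9338004": 1}
  - label: A
    requires: {"6:9336861": 0, "6:9337236": 0, "6:9338004": 0}
  activity: {A: 1, B: 1, C: 0, D: 0}
- name: Hd2
  chromosome: 7
  effect_sign: "+"
  haplotypes:
  - label: L    # reference, functional long-day repressor (late heading)
    requires: {"7:29623803": 0}
  - label: E    # alternative, non-functional (early heading)
    requires: {"7:29623803": 1}
  activity: {L: 1, E: 0}
- name: Hd6
  chromosome: 3
  effect_sign: "+"
  haplotypes:
  - label: E    # reference, non-functional (early heading)
    requires: {"3:31512460": 0}
  - label: L    # alternative, functional repressor (late heading)
    requires: {"3:31512460": 1}
  activity: {L: 1, E: 0}
- name: Hd16
  chromosome: 3
  effect_sign: "+"
  haplotypes:
  - label: L    # reference, functional repressor (late heading)
    requires: {"3:33002789": 0}
  - label: E    # alternative, non-functional (early heading)
    requires: {"3:33002789": 1}
  activity: {L: 1, E: 0}
- name: Hd17
  chromosome: 6
  effect_sign: "-"
  haplotypes:
  - label: E    # reference, functional promoter (early heading)
    requires: {"6:2235191": 0}
  - label: L    # alternative, low-function (late heading)
    requires: {"6:2235191": 1}
  activity: {E: 1, L: 0}
- name: Hd18
  chromosome: 8
  effect_sign: "-"
  haplotypes:
  - label: E    # reference, high-functional promoter (early heading)
    requires: {"8:2388554": 0}
  - label: L    # alternative, functional (later heading)
    requires: {"8:2388554": 1}
  activity: {E: 1, L: 0}
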