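"""Hand-parsed fixture sentences with hand-traced golden feature sets.

Each fixture is a small dependency-parsed sentence, the token indices of the
two gene mentions forming the candidate, and the complete expected feature
set, traced by hand from the template rules (windows, between-span, verbs,
shortest dependency path, prepositional attachment, masking).  The expected
sets were written from the rules, not from the implementation, and are
compared exactly.
"""

from genelink.corpus_io import ParsedSentence, Token

# token spec: (word, lemma, pos, dep_head, dep_label)


def sent(doc_id, sent_index, specs):
    return ParsedSentence(
        doc_id=doc_id,
        sent_index=sent_index,
        tokens=tuple(
            Token(index=i, word=w, lemma=l, pos=p, ner="", dep_head=h, dep_label=d)
            for i, (w, l, p, h, d) in enumerate(specs)
        ),
    )


GOLDEN = [
    (
        "simple_transitive_bind",
        sent("g1", 0, [
            ("GRB2", "GRB2", "NNP", 1, "nsubj"),
            ("binds", "bind", "VBZ", -1, "root"),
            ("SOS1", "SOS1", "NNP", 1, "dobj"),
            (".", ".", ".", 1, "punct"),
        ]),
        (0, 2),
        {
            "Window_Right_Gene1_1gram_[binds]",
            "Window_Right_Gene1_2gram_[binds GENE]",
            "Window_Right_Gene1_Phrase_[binds GENE]",
            "Window_Left_Gene2_1gram_[binds]",
            "Window_Left_Gene2_2gram_[GENE binds]",
            "Window_Left_Gene2_Phrase_[GENE binds]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[binds]",
            "Verb_Between_Genes_[bind]",
            "Single_Verb_Between_Genes_[bind]",
            "Verb_On_Dependency_Path_[bind]",
            "Dependency_Path_[GENE ^nsubj bind vdobj GENE]",
            "Collapsed_Dependency_Path_[GENE—VERB—GENE]",
        },
    ),
    (
        "interaction_between_collapsed_preps",
        sent("g2", 0, [
            ("interaction", "interaction", "NN", -1, "root"),
            ("between", "between", "IN", 0, "prep"),
            ("TP53", "TP53", "NNP", 0, "prep_between"),
            ("and", "and", "CC", 2, "cc"),
            ("MDM2", "MDM2", "NNP", 0, "prep_between"),
            (".", ".", ".", 0, "punct"),
        ]),
        (2, 4),
        {
            "Window_Left_Gene1_1gram_[between]",
            "Window_Left_Gene1_2gram_[interaction between]",
            "Window_Left_Gene1_Phrase_[interaction between]",
            "Window_Right_Gene1_1gram_[and]",
            "Window_Right_Gene1_2gram_[and GENE]",
            "Window_Right_Gene1_Phrase_[and GENE]",
            "Window_Left_Gene2_1gram_[and]",
            "Window_Left_Gene2_2gram_[GENE and]",
            "Window_Left_Gene2_Phrase_[GENE and]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[and]",
            "Dependency_Path_[GENE ^prep_between interaction vprep_between GENE]",
            "Collapsed_Dependency_Path_[GENE—NOUN—GENE]",
            "Prep_Pattern_[interaction between between]",
        },
    ),
    (
        "binding_of_to_basic_preps",
        sent("g3", 0, [
            ("binding", "binding", "NN", -1, "root"),
            ("of", "of", "IN", 0, "prep"),
            ("CDK2", "CDK2", "NNP", 1, "pobj"),
            ("to", "to", "IN", 0, "prep"),
            ("CCNE1", "CCNE1", "NNP", 3, "pobj"),
            (".", ".", ".", 0, "punct"),
        ]),
        (2, 4),
        {
            "Window_Left_Gene1_1gram_[of]",
            "Window_Left_Gene1_2gram_[binding of]",
            "Window_Left_Gene1_Phrase_[binding of]",
            "Window_Right_Gene1_1gram_[to]",
            "Window_Right_Gene1_2gram_[to GENE]",
            "Window_Right_Gene1_Phrase_[to GENE]",
            "Window_Left_Gene2_1gram_[to]",
            "Window_Left_Gene2_2gram_[GENE to]",
            "Window_Left_Gene2_Phrase_[GENE to]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[to]",
            "Dependency_Path_[GENE ^pobj of ^prep binding vprep to vpobj GENE]",
            "Collapsed_Dependency_Path_[GENE—OTHER—NOUN—OTHER—GENE]",
            "Prep_Pattern_[binding of to]",
        },
    ),
    (
        "negation_two_verbs_between",
        sent("g4", 0, [
            ("ABL1", "ABL1", "NNP", 3, "nsubj"),
            ("does", "do", "VBZ", 3, "aux"),
            ("not", "not", "RB", 3, "neg"),
            ("interact", "interact", "VB", -1, "root"),
            ("with", "with", "IN", 3, "prep"),
            ("CRKL", "CRKL", "NNP", 4, "pobj"),
            (".", ".", ".", 3, "punct"),
        ]),
        (0, 5),
        {
            "Window_Right_Gene1_1gram_[does]",
            "Window_Right_Gene1_2gram_[does not]",
            "Window_Right_Gene1_Phrase_[does not]",
            "Window_Left_Gene2_1gram_[with]",
            "Window_Left_Gene2_2gram_[interact with]",
            "Window_Left_Gene2_Phrase_[interact with]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[does not interact with]",
            "Verb_Between_Genes_[do]",
            "Verb_Between_Genes_[interact]",
            "Verb_On_Dependency_Path_[interact]",
            "Dependency_Path_[GENE ^nsubj interact vprep with vpobj GENE]",
            "Collapsed_Dependency_Path_[GENE—VERB—OTHER—GENE]",
        },
    ),
    (
        "adjacent_mentions_empty_between",
        sent("g5", 0, [
            ("KRAS", "KRAS", "NNP", 3, "nn"),
            ("BRAF", "BRAF", "NNP", 3, "nn"),
            ("signaling", "signaling", "NN", 3, "nn"),
            ("pathway", "pathway", "NN", -1, "root"),
            (".", ".", ".", 3, "punct"),
        ]),
        (0, 1),
        {
            "Window_Right_Gene1_1gram_[GENE]",
            "Window_Right_Gene1_2gram_[GENE signaling]",
            "Window_Right_Gene1_Phrase_[GENE signaling]",
            "Window_Left_Gene2_1gram_[GENE]",
            "Window_Left_Gene2_2gram_[GENE]",
            "Window_Left_Gene2_Phrase_[GENE]",
            "Window_Right_Gene2_1gram_[signaling]",
            "Window_Right_Gene2_2gram_[signaling pathway]",
            "Window_Right_Gene2_Phrase_[signaling pathway]",
            "Dependency_Path_[GENE ^nn pathway vnn GENE]",
            "Collapsed_Dependency_Path_[GENE—NOUN—GENE]",
        },
    ),
    (
        "disconnected_parse_fragments",
        sent("g6", 0, [
            ("EGFR", "EGFR", "NNP", -1, "root"),
            (".", ".", ".", 0, "punct"),
            ("ERBB2", "ERBB2", "NNP", -1, "root"),
            ("fragment", "fragment", "NN", 2, "nn"),
        ]),
        (0, 2),
        {
            "Window_Right_Gene1_1gram_[.]",
            "Window_Right_Gene1_2gram_[. GENE]",
            "Window_Right_Gene1_Phrase_[. GENE]",
            "Window_Left_Gene2_1gram_[.]",
            "Window_Left_Gene2_2gram_[GENE .]",
            "Window_Left_Gene2_Phrase_[GENE .]",
            "Window_Right_Gene2_1gram_[fragment]",
            "Window_Right_Gene2_2gram_[fragment]",
            "Window_Right_Gene2_Phrase_[fragment]",
            "Phrase_Between_Genes_[.]",
        },
    ),
    (
        "three_genes_outer_pair_third_unmasked",
        sent("g7", 0, [
            ("RAF1", "RAF1", "NNP", 1, "nsubj"),
            ("activates", "activate", "VBZ", -1, "root"),
            ("MEK1", "MEK1", "NNP", 1, "dobj"),
            ("and", "and", "CC", 2, "cc"),
            ("ERK2", "ERK2", "NNP", 2, "conj"),
            (".", ".", ".", 1, "punct"),
        ]),
        (0, 4),
        {
            "Window_Right_Gene1_1gram_[activates]",
            "Window_Right_Gene1_2gram_[activates MEK1]",
            "Window_Right_Gene1_Phrase_[activates MEK1]",
            "Window_Left_Gene2_1gram_[and]",
            "Window_Left_Gene2_2gram_[MEK1 and]",
            "Window_Left_Gene2_Phrase_[MEK1 and]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[activates MEK1 and]",
            "Verb_Between_Genes_[activate]",
            "Single_Verb_Between_Genes_[activate]",
            "Verb_On_Dependency_Path_[activate]",
            "Dependency_Path_[GENE ^nsubj activate vdobj MEK1 vconj GENE]",
            "Collapsed_Dependency_Path_[GENE—VERB—NOUN—GENE]",
        },
    ),
    (
        "three_genes_inner_pair_direct_conj_edge",
        sent("g7", 0, [
            ("RAF1", "RAF1", "NNP", 1, "nsubj"),
            ("activates", "activate", "VBZ", -1, "root"),
            ("MEK1", "MEK1", "NNP", 1, "dobj"),
            ("and", "and", "CC", 2, "cc"),
            ("ERK2", "ERK2", "NNP", 2, "conj"),
            (".", ".", ".", 1, "punct"),
        ]),
        (2, 4),
        {
            "Window_Left_Gene1_1gram_[activates]",
            "Window_Left_Gene1_2gram_[RAF1 activates]",
            "Window_Left_Gene1_Phrase_[RAF1 activates]",
            "Window_Right_Gene1_1gram_[and]",
            "Window_Right_Gene1_2gram_[and GENE]",
            "Window_Right_Gene1_Phrase_[and GENE]",
            "Window_Left_Gene2_1gram_[and]",
            "Window_Left_Gene2_2gram_[GENE and]",
            "Window_Left_Gene2_Phrase_[GENE and]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[and]",
            "Dependency_Path_[GENE vconj GENE]",
            "Collapsed_Dependency_Path_[GENE—GENE]",
        },
    ),
    (
        "long_between_span_suppresses_phrase",
        sent("g8", 0, [
            ("STAT3", "STAT3", "NNP", 3, "nsubj"),
            ("is", "be", "VBZ", 3, "cop"),
            ("a", "a", "DT", 3, "det"),
            ("factor", "factor", "NN", -1, "root"),
            ("that", "that", "WDT", 6, "nsubj"),
            ("strongly", "strongly", "RB", 6, "advmod"),
            ("regulates", "regulate", "VBZ", 3, "rcmod"),
            ("the", "the", "DT", 8, "det"),
            ("oncogene", "oncogene", "NN", 9, "nn"),
            ("MYC", "MYC", "NNP", 6, "dobj"),
            (".", ".", ".", 3, "punct"),
        ]),
        (0, 9),
        {
            "Window_Right_Gene1_1gram_[is]",
            "Window_Right_Gene1_2gram_[is a]",
            "Window_Right_Gene1_Phrase_[is a]",
            "Window_Left_Gene2_1gram_[oncogene]",
            "Window_Left_Gene2_2gram_[the oncogene]",
            "Window_Left_Gene2_Phrase_[the oncogene]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Verb_Between_Genes_[be]",
            "Verb_Between_Genes_[regulate]",
            "Verb_On_Dependency_Path_[regulate]",
            "Dependency_Path_[GENE ^nsubj factor vrcmod regulate vdobj GENE]",
            "Collapsed_Dependency_Path_[GENE—NOUN—VERB—GENE]",
        },
    ),
    (
        "no_trailing_punctuation",
        sent("g9", 0, [
            ("TP53", "TP53", "NNP", 1, "nsubj"),
            ("suppresses", "suppress", "VBZ", -1, "root"),
            ("MDM2", "MDM2", "NNP", 1, "dobj"),
        ]),
        (0, 2),
        {
            "Window_Right_Gene1_1gram_[suppresses]",
            "Window_Right_Gene1_2gram_[suppresses GENE]",
            "Window_Right_Gene1_Phrase_[suppresses GENE]",
            "Window_Left_Gene2_1gram_[suppresses]",
            "Window_Left_Gene2_2gram_[GENE suppresses]",
            "Window_Left_Gene2_Phrase_[GENE suppresses]",
            "Phrase_Between_Genes_[suppresses]",
            "Verb_Between_Genes_[suppress]",
            "Single_Verb_Between_Genes_[suppress]",
            "Verb_On_Dependency_Path_[suppress]",
            "Dependency_Path_[GENE ^nsubj suppress vdobj GENE]",
            "Collapsed_Dependency_Path_[GENE—VERB—GENE]",
        },
    ),
    (
        "truncated_left_window_at_index_one",
        sent("g10", 0, [
            ("the", "the", "DT", 2, "det"),
            ("AKT1", "AKT1", "NNP", 2, "nn"),
            ("pathway", "pathway", "NN", 3, "nsubj"),
            ("inhibits", "inhibit", "VBZ", -1, "root"),
            ("FOXO3", "FOXO3", "NNP", 3, "dobj"),
            (".", ".", ".", 3, "punct"),
        ]),
        (1, 4),
        {
            "Window_Left_Gene1_1gram_[the]",
            "Window_Left_Gene1_2gram_[the]",
            "Window_Left_Gene1_Phrase_[the]",
            "Window_Right_Gene1_1gram_[pathway]",
            "Window_Right_Gene1_2gram_[pathway inhibits]",
            "Window_Right_Gene1_Phrase_[pathway inhibits]",
            "Window_Left_Gene2_1gram_[inhibits]",
            "Window_Left_Gene2_2gram_[pathway inhibits]",
            "Window_Left_Gene2_Phrase_[pathway inhibits]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[pathway inhibits]",
            "Verb_Between_Genes_[inhibit]",
            "Single_Verb_Between_Genes_[inhibit]",
            "Verb_On_Dependency_Path_[inhibit]",
            "Dependency_Path_[GENE ^nn pathway ^nsubj inhibit vdobj GENE]",
            "Collapsed_Dependency_Path_[GENE—NOUN—VERB—GENE]",
        },
    ),
    (
        "ud_style_nmod_preps",
        sent("g11", 0, [
            ("association", "association", "NN", -1, "root"),
            ("of", "of", "IN", 2, "case"),
            ("SMAD2", "SMAD2", "NNP", 0, "nmod:of"),
            ("with", "with", "IN", 4, "case"),
            ("SMAD4", "SMAD4", "NNP", 0, "nmod:with"),
            (".", ".", ".", 0, "punct"),
        ]),
        (2, 4),
        {
            "Window_Left_Gene1_1gram_[of]",
            "Window_Left_Gene1_2gram_[association of]",
            "Window_Left_Gene1_Phrase_[association of]",
            "Window_Right_Gene1_1gram_[with]",
            "Window_Right_Gene1_2gram_[with GENE]",
            "Window_Right_Gene1_Phrase_[with GENE]",
            "Window_Left_Gene2_1gram_[with]",
            "Window_Left_Gene2_2gram_[GENE with]",
            "Window_Left_Gene2_Phrase_[GENE with]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[with]",
            "Dependency_Path_[GENE ^nmod:of association vnmod:with GENE]",
            "Collapsed_Dependency_Path_[GENE—NOUN—GENE]",
            "Prep_Pattern_[association of with]",
        },
    ),
    (
        "repeated_partner_symbol_masked_everywhere",
        sent("g12", 0, [
            ("TP53", "TP53", "NNP", 3, "nsubj"),
            ("and", "and", "CC", 0, "cc"),
            ("MDM2", "MDM2", "NNP", 0, "conj"),
            ("form", "form", "VBP", -1, "root"),
            ("the", "the", "DT", 6, "det"),
            ("TP53", "TP53", "NNP", 6, "nn"),
            ("complex", "complex", "NN", 3, "dobj"),
            (".", ".", ".", 3, "punct"),
        ]),
        (2, 5),
        {
            "Window_Left_Gene1_1gram_[and]",
            "Window_Left_Gene1_2gram_[GENE and]",
            "Window_Left_Gene1_Phrase_[GENE and]",
            "Window_Right_Gene1_1gram_[form]",
            "Window_Right_Gene1_2gram_[form the]",
            "Window_Right_Gene1_Phrase_[form the]",
            "Window_Left_Gene2_1gram_[the]",
            "Window_Left_Gene2_2gram_[form the]",
            "Window_Left_Gene2_Phrase_[form the]",
            "Window_Right_Gene2_1gram_[complex]",
            "Window_Right_Gene2_2gram_[complex .]",
            "Window_Right_Gene2_Phrase_[complex .]",
            "Phrase_Between_Genes_[form the]",
            "Verb_Between_Genes_[form]",
            "Single_Verb_Between_Genes_[form]",
            "Verb_On_Dependency_Path_[form]",
            "Dependency_Path_[GENE ^conj GENE ^nsubj form vdobj complex vnn GENE]",
            "Collapsed_Dependency_Path_[GENE—NOUN—VERB—NOUN—GENE]",
        },
    ),
    (
        "verb_governed_prep_no_prep_pattern",
        sent("g13", 0, [
            ("PTEN", "PTEN", "NNP", 1, "nsubj"),
            ("works", "work", "VBZ", -1, "root"),
            ("with", "with", "IN", 1, "prep"),
            ("AKT1", "AKT1", "NNP", 2, "pobj"),
            (".", ".", ".", 1, "punct"),
        ]),
        (0, 3),
        {
            "Window_Right_Gene1_1gram_[works]",
            "Window_Right_Gene1_2gram_[works with]",
            "Window_Right_Gene1_Phrase_[works with]",
            "Window_Left_Gene2_1gram_[with]",
            "Window_Left_Gene2_2gram_[works with]",
            "Window_Left_Gene2_Phrase_[works with]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[works with]",
            "Verb_Between_Genes_[work]",
            "Single_Verb_Between_Genes_[work]",
            "Verb_On_Dependency_Path_[work]",
            "Dependency_Path_[GENE ^nsubj work vprep with vpobj GENE]",
            "Collapsed_Dependency_Path_[GENE—VERB—OTHER—GENE]",
        },
    ),
    (
        "delimiter_characters_sanitized",
        sent("g14", 0, [
            ("OC1", "OC1", "NNP", 2, "nsubj"),
            ("ref]", "ref]", "NN", 0, "dep"),
            ("binds", "bind", "VBZ", -1, "root"),
            ("OC2", "OC2", "NNP", 2, "dobj"),
            (".", ".", ".", 2, "punct"),
        ]),
        (0, 3),
        {
            "Window_Right_Gene1_1gram_[ref)]",
            "Window_Right_Gene1_2gram_[ref) binds]",
            "Window_Right_Gene1_Phrase_[ref) binds]",
            "Window_Left_Gene2_1gram_[binds]",
            "Window_Left_Gene2_2gram_[ref) binds]",
            "Window_Left_Gene2_Phrase_[ref) binds]",
            "Window_Right_Gene2_1gram_[.]",
            "Window_Right_Gene2_2gram_[.]",
            "Window_Right_Gene2_Phrase_[.]",
            "Phrase_Between_Genes_[ref) binds]",
            "Verb_Between_Genes_[bind]",
            "Single_Verb_Between_Genes_[bind]",
            "Verb_On_Dependency_Path_[bind]",
            "Dependency_Path_[GENE ^nsubj bind vdobj GENE]",
            "Collapsed_Dependency_Path_[GENE—VERB—GENE]",
        },
    ),
]
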