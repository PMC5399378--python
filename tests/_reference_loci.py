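"""Published reference loci for conserved miRNA precursors: locus
string, family, printed mature sequence(s), precursor length (nt) and
folding MFE (kcal/mol).  Used as frozen expected values."""

REFERENCE_LOCI = [
    ('S648_2373-2295:-', 'let-7', 'UGAGGUAGUAGGUUGUAUAGUUU', 79, -30.4),
    ('S93_67805-67726:-', 'let-7', 'UGAGGUAGUGGAUUAUGCAGUU', 80, -30.1),
    ('S93_68361-68283:-', 'let-7', 'UGAGGUAGUAGGUUAUAUCAGU', 79, -22.6),
    ('S93_68526-68445:-', 'let-7', 'UGAGGUAGUAGGUUAUGUAGUG', 82, -24.6),
    ('S93_68698-68609:-', 'let-7', 'CUGAGGUAGUAGGUUAUGCAGUU', 90, -31.2),
    ('S24_284667-284752:+', 'miR-7', 'UGGAAGACUAGUGAUUUUGUUGUUC', 86, -19.5),
    ('S159_72225-72288:+', 'miR-9', 'UCUUUGGUUAUCUAGUUUUGUG', 64, -20.3),
    ('S93_128856-128791:-', 'miR-29', 'UAGCACCAUUGGAAAUCGGUC', 66, -19.8),
    ('S65_9585-9666:+', 'miR-31', 'UAUGGCAAGAUGUUGGCAUAGCUGC', 82, -34.0),
    ('S298_83663-83598:-', 'miR-33', 'AAGUGCAUUGUAGUUGCAUUGCACA', 66, -20.8),
    ('S160_170587-170662:+', 'miR-34', 'AGGCAGUGUAGUUAGCUAGUUG', 76, -19.3),
    ('S27_318389-318451:+', 'miR-92', 'UAUUGCACUUGUCCCGGCCU', 63, -18.8),
    ('S57_155850-155929:+', 'miR-92', 'UAUUGCACUCGUCCCGGUCUAU', 80, -21.5),
    ('S181_161093-161016:-', 'miR-96', 'UUUGGCACUAGCACAUUAUU', 78, -25.2),
    ('S375_52432-52351:-', 'miR-124', 'CGUGUUCACUGCAGACCUU,CAUUAAGGCACGCGGUGAAUGCUAU', 82, -30.0),
    ('S375_52641-52557:-', 'miR-124', 'AAUUAAGGCACGCGGUGAAUGCCAGA', 85, -37.6),
    ('S375_60909-60992:+', 'miR-124', 'UAUUAAGGCACGCGGUGAAUGCCAAG', 84, -37.0),
    ('S60_145419-145497:+', 'miR-126', 'CCUUGUUACUUACGGUACC,AUCUCGUACCGUGAGUAAUAAAGCU', 79, -38.2),
    ('S6_131727-131818:+', 'miR-133', 'GCUGGUCAACCGGAACCAAAUC,UUUGGUCCCCUUCAACCAGCUGUU', 92, -29.5),
    ('S56_118756-118667:-', 'miR-135', 'UAUGGCUUUAUUUAUUCCUGUGUGA', 90, -32.9),
    ('S67_157861-157774:-', 'miR-153', 'GUCAUUUUUGUAUUAUGCAA,UUGCAUAGUAACAAAAGUGAUCAU', 88, -40.3),
    ('S181_160894-160804:-', 'miR-182', 'CUUGGCAAAAUAUAGAACUC', 91, -36.1),
    ('S181_165741-165631:-', 'miR-183', 'UAUGGCACUAGUAGAAUUCACUGC', 111, -36.3),
    ('S602_41811-41890:+', 'miR-184', 'UGGACGGAGAAUUGAUAAGGAA', 80, -30.4),
    ('S54_165680-165756:+', 'miR-196', 'UAGGUAGUUACAAGUUGUGG', 77, -25.6),
    ('S353_78598-78518:-', 'miR-200', 'UAAUACUGCUUGGUAAUGAUGAU', 81, -24.5),
    ('S244_68891-68803:-', 'miR-216', 'UAAUCUCAGCUGGCAAUCUGUGA', 89, -35.3),
    ('S244_68624-68517:-', 'miR-217', 'AUACUGCAUUAGGAACUGAUUGGU', 108, -30.3),
    ('S248_20812-20705:-', 'miR-218', 'UAUGUGCUUUGAUCUAACCAUGU', 108, -34.9),
    ('S21_373535-373467:-', 'miR-219', 'UGAUUGUCCAAACGCAAUUCGCG', 69, -19.3),
    ('S11_93983-94061:+', 'miR-281', 'UGUCAUGGAGUUGCUCUCUUAUU', 79, -24.3),
    ('S99_176620-176695:+', 'miR-367', 'UAUUGCACAUUGUAAUGGUA', 76, -29.3),
    ('S291_113322-113388:+', 'miR-1497', 'UUGAAGAAUUGCAGGUGGUAGGU', 67, -23.2),
    ('S290_113331-113406:+', 'miR-1502', 'UUGAACUUUCUAAGGAAUAG', 76, -30.2),
    ('S19_110094-110150:+', 'miR-3182', 'GCUUUUGUAGUUUAGUC', 57, -20.4),
    ('S210_48343-48421:+', 'miR-3598', 'UCACAGUGGUUGUAUACUGC', 79, -42.1),
    ('S176_129704-129781:+', 'miR-3876', 'GUUUUGUUUUAACACUUAC', 78, -22.4),
]
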