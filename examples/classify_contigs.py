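"""Classify a small annotation table into archaeal-virus categories.

Builds a four-contig gene-per-contig annotation table in memory, runs the
majority-rules classifier with default thresholds, and prints each
contig's category with its evidence profile.
"""

from marvd import classify_table, parse_annotation_table

TABLE = """\
contig_id\tgene_id\tgene_index\tlineage\tbit_score\te_value
long\tlong_1\t1\tSulfolobus spindle-shaped virus 1\t150\t1e-40
long\tlong_2\t2\t\t\t
long\tlong_3\t3\tAcidianus two-tailed virus\t96\t1e-20
long\tlong_4\t4\t\t\t
mosaic\tmosaic_1\t1\tHaloarcula hispanica virus SH1\t90\t1e-18
mosaic\tmosaic_2\t2\tHalorubrum pleomorphic virus 1\t85\t1e-16
mosaic\tmosaic_3\t3\tThermoproteus tenax virus 1\t88\t1e-17
mosaic\tmosaic_4\t4\tEnterobacteria phage T4\t130\t1e-35
minority\tminority_1\t1\tSulfolobus virus STSV2\t110\t1e-25
minority\tminority_2\t2\tHaloferax virus HF2\t88\t1e-15
minority\tminority_3\t3\tPseudomonas phage phiKZ\t80\t1e-14
plain\tplain_1\t1\tEnterobacteria phage T4\t200\t1e-50
plain\tplain_2\t2\tVibrio phage KVP40\t150\t1e-40
plain\tplain_3\t3\tMycobacterium phage L5\t120\t1e-30
"""

result = classify_table(parse_annotation_table(TABLE))
print(result.to_frame()[["contig_id", "category", "n_genes", "n_annotated",
                         "arch_fraction", "max_bit_archaeal_virus",
                         "max_bit_phage"]].to_string(index=False))
print()
print("Category 1 = confident archaeal virus (archaeal majority, best bits);")
print("2 = archaeal majority but one phage hit scores higher (mosaic);")
print("3 = archaeal minority whose annotation quality beats the phage hits;")
print("'none' = rejected. 'long' enters category 1 through the 1-2-annotation")
print("clause even though only 2 of its 4 genes could be annotated.")
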