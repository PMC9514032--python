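# Default curated catalog of transcription- and translation-machinery genes.
# Seeded from the highest-frequency cassette genes reported for prokaryotic
# transcription-translation coupling (RNA polymerase subunits, Nus factors,
# ribosomal proteins, initiation factors, Sec translocase components).
# Dual-role coupling factors (nusA, nusG) are filed under transcription; a
# cassette mixing them with ribosomal genes is classified "both" downstream.
# columns: canonical_gene, category, synonyms (";"-joined),
#          function_keywords (";"-joined), cog_ids (";"-joined)
canonical_gene	category	synonyms	function_keywords	cog_ids
rpoA	transcription		DNA-directed RNA polymerase subunit alpha	COG0202K
rpoB	transcription		DNA-directed RNA polymerase subunit beta
nusA	transcription		transcription elongation factor NusA	COG0195K
nusG	transcription		transcription termination/antitermination protein NusG;transcription termination factor	COG0250K
mfd	transcription		transcription-repair coupling factor	COG1197LK
rplQ	translation		50S ribosomal protein L17	COG0203J
rpsM	translation		30S ribosomal protein S13	COG0099J
rpsK	translation		30S ribosomal protein S11	COG0100J
rpsD	translation		30S ribosomal protein S4	COG0522J
rplK	translation		50S ribosomal protein L11	COG0080J
rplA	translation		50S ribosomal protein L1	COG0081J
rbfA	translation		ribosome-binding factor A	COG0858J
rpmJ	translation		50S ribosomal protein L36	COG0257J
rplO	translation		50S ribosomal protein L15	COG0200J
rplR	translation		50S ribosomal protein L18
rpsE	translation		30S ribosomal protein S5
rpsH	translation		30S ribosomal protein S8
truB	translation		tRNA pseudouridine synthase B	COG0130J
infA	translation		translation initiation factor IF-1	COG0361J
infB	translation		translation initiation factor IF-2	COG0532J
secE	translation		preprotein translocase subunit SecE	COG0690U
secY	translation		preprotein translocase subunit SecY	COG0201U
rimP	translation	yhbC	ribosome maturation factor RimP	COG0779S
ylxR	translation		nucleoid-associated protein YlxR	COG2740K
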