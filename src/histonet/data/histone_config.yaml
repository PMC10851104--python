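# Histone identification config: per-type entity-name keywords and a
# reference sequence used for the sequence-identity fallback.  Users may
# supply their own file with the same layout; this default approximates the
# keyword lists commonly used for PDB text searches.
identity_threshold: 0.6
types:
  H1:
    keywords:
      - histone h1
      - histone h5
      - linker histone
      - "h1."
    reference: >-
      TENSTSAPAAKPKRAKASKKSTDHPKYSDMIVAAIQAEKNRAGSSRQSIQKYIKSHYKVG
      ENADSQIKLSIKRLVTTGVLKQTKGVGASGSFRLAKSDEPKKSVAFKKTKKEIKKVATPK
      KASKPKKAASKAPTKKPKATPVKKAKKKLAATPKKAKKPKTVKAKPVKASKPKKAKPVKP
      KAKSSAKRAGKKK
  H2A:
    keywords:
      - histone h2a
      - h2a.z
      - h2a.x
      - macroh2a
      - "h2a type"
    reference: >-
      SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTA
      EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
      ESHHKAKGK
  H2B:
    keywords:
      - histone h2b
      - "h2b type"
    reference: >-
      PEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKESYSVYVYKVLKQVHPDTGISSKAMG
      IMNSFVNDIFERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVTK
      YTSSK
  H3:
    keywords:
      - histone h3
      - "h3."
      - cenp-a
      - centromeric histone
    reference: >-
      ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTEL
      LIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTIM
      PKDIQLARRIRGERA
  H4:
    keywords:
      - histone h4
    reference: >-
      SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKV
      FLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
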