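taxon,petA,psaM,infA,LIPOR,petD_trans,psaA_trans,psaC_trans,psaC_intron@25
Oedogonium_cardiacum,0,1,1,1,1,0,1,1
Oedogonium_angustistomum,0,1,1,1,1,0,1,1
Koshicola_spirodelophila,0,1,1,1,1,0,1,1
Chaetopeltis_orbicularis,0,1,1,1,1,0,1,1
Floydiella_terrestris,0,1,1,1,1,0,1,1
Schizomeris_leibleinii,0,1,0,1,1,0,1,1
Uronema_sp,0,1,0,1,1,0,1,1
Stigeoclonium_helveticum,0,1,0,1,1,0,1,1
Hafniomonas_laevis,1,0,0,0,0,1,0,0
Carteria_cerasiformis,1,0,0,1,0,0,0,0
Carteria_sp,1,0,0,1,0,1,0,1
Borodinellopsis_texensis,1,0,0,1,0,1,0,1
Chloromonas_rosae,1,0,0,1,0,1,0,0
Microglena_monadina,1,0,0,1,0,1,0,0
Phacotus_lenticularis,1,0,0,1,0,1,0,0
Desmotetra_stigmatica,1,0,0,1,0,1,0,0
Protosiphon_botryoides,1,0,0,1,0,1,0,0
Chlorococcum_tatrense,1,0,0,1,0,1,0,0
Chlorosarcinopsis_eremi,1,0,0,1,0,1,0,0
Spermatozopsis_similis,1,0,1,1,0,1,0,0
Atractomorpha_echinata,1,0,1,1,0,1,0,0
Ankyra_judayi,1,0,1,1,0,1,0,0
Cylindrocapsa_geminella,1,0,1,1,0,1,0,0
Elakatothrix_viridis,1,0,1,1,0,1,0,1
Trochiscia_hystrix,1,0,1,1,0,1,0,0
Dictyochloris_fragrans,1,0,1,1,0,1,0,1
Microspora_sp,1,0,1,1,0,1,0,0
Parallela_transversalis,1,0,1,1,0,1,0,0
Jenufa_perforata,1,0,1,1,0,1,0,1
Golenkinia_longispicula,1,0,1,0,0,1,0,0
Mychonastes_homosphaera,1,0,1,1,0,1,0,0
Mychonastes_jurisii,1,0,1,1,0,1,0,0
Chromochloris_zofingiensis,1,0,1,1,0,1,0,0
Pseudomuriella_schumacherensis,1,0,1,1,0,1,0,0
Bracteacoccus_minor,1,0,1,1,0,1,0,0
Follicularia_botryoides,1,0,1,1,0,1,0,0
Tetradesmus_obliquus,1,0,1,1,0,1,0,0
Neochloris_aquatica,1,0,1,0,0,1,0,0
Chlorotetraedron_incus,1,0,1,1,0,1,0,0
Pediastrum_duplex,1,0,1,1,0,1,0,0
!position,,,,,,,25,25
!splicing,,,,,trans,trans,trans,unknown
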