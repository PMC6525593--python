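(((Oedogonium_cardiacum,Oedogonium_angustistomum),((Koshicola_spirodelophila,(Chaetopeltis_orbicularis,Floydiella_terrestris)),(Schizomeris_leibleinii,(Uronema_sp,Stigeoclonium_helveticum)))),((Hafniomonas_laevis,((Carteria_cerasiformis,Carteria_sp),(Borodinellopsis_texensis,(Chloromonas_rosae,(Microglena_monadina,(Phacotus_lenticularis,(Desmotetra_stigmatica,(Protosiphon_botryoides,(Chlorococcum_tatrense,Chlorosarcinopsis_eremi))))))))),((Spermatozopsis_similis,(Atractomorpha_echinata,Ankyra_judayi)),(((Cylindrocapsa_geminella,(Elakatothrix_viridis,Trochiscia_hystrix)),((Dictyochloris_fragrans,(Microspora_sp,Parallela_transversalis)),(Jenufa_perforata,Golenkinia_longispicula))),((Mychonastes_homosphaera,Mychonastes_jurisii),(Chromochloris_zofingiensis,(Pseudomuriella_schumacherensis,((Bracteacoccus_minor,Follicularia_botryoides),(Tetradesmus_obliquus,((Neochloris_aquatica,Chlorotetraedron_incus),Pediastrum_duplex))))))))));
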