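section,division,code,group
provisioning,Nutrition,1.1.1,Biomass
provisioning,Nutrition,1.1.2,Water
provisioning,Materials,1.2.1,Biomass
provisioning,Materials,1.2.2,Water
provisioning,Materials,1.2.3,Metallic and non-metallic abiotic materials
provisioning,Energy,1.3.1,Biomass
provisioning,Energy,1.3.2,Renewable abiotic source
provisioning,Energy,1.3.3,Non-renewable abiotic source
regulation_support,"Regulation of waste, toxic substances, and other nuisances",2.1.1,Mediation by living systems
regulation_support,Flow regulation,2.2.1,Mass flows
regulation_support,Flow regulation,2.2.2,Liquid flows
regulation_support,Flow regulation,2.2.3,Gas/air flows
regulation_support,"Maintenance of physical, chemical, and biological conditions",2.3.1,"Maintenance of the life cycle, habitat, and protection of the gene pool"
regulation_support,"Maintenance of physical, chemical, and biological conditions",2.3.2,Control of pests and diseases
regulation_support,"Maintenance of physical, chemical, and biological conditions",2.3.3,Soil formation and composition
regulation_support,"Maintenance of physical, chemical, and biological conditions",2.3.4,Maintenance of the chemical composition of water
regulation_support,"Maintenance of physical, chemical, and biological conditions",2.3.5,Atmospheric composition and climate regulation
cultural,Physical and intellectual interaction,3.1.1,Physical experience
cultural,Physical and intellectual interaction,3.1.2,Intellectual and representative
cultural,Symbolic and spiritual interaction,3.2.1,Spiritual or emblematic
cultural,Symbolic and spiritual interaction,3.2.2,Existence and natural intrinsic value
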